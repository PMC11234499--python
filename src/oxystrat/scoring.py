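"""Hypoxia metagene scoring and stratification.

The score follows the Buffa metagene rule: for each signature gene present in
the matrix, a sample contributes +1 if its expression is strictly above that
gene's across-cohort median and -1 otherwise; the score is the sum over
signature genes, an integer in ``[-G, +G]`` with the parity of ``G`` (the
number of signature genes found in the matrix). Because only within-gene
ranks matter, the score is invariant to any per-gene strictly monotone
transform of the expression values (log2, TPM rescaling, ...).

The same rule is applied to every gene list (Buffa-style by default; any GMT
set can be substituted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateScoresError, DuplicateIdError, SignatureOverlapError

__all__ = [
    "GeneSignature",
    "HypoxiaScores",
    "StratumAssignment",
    "read_gmt",
    "bundled_signatures",
    "score_signature",
    "stratify",
    "score_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSignature:
    """A named set of (hypoxia-induced) gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise DuplicateIdError(f"signature {self.name!r} has duplicate symbols")


@dataclass
class HypoxiaScores:
    """Per-sample integer metagene scores.

    ``scores`` is indexed by sample id; ``n_genes_used`` is G, the number of
    signature genes actually found in the expression matrix.
    """

    scores: pd.Series
    n_genes_used: int
    signature: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.scores.index, "score": self.scores.to_numpy()}
        )


@dataclass
class StratumAssignment:
    """Low/medium/high (tertile mode) or low/high (median mode) strata."""

    strata: pd.Series  # sample id -> stratum label
    cutoffs: tuple[float, ...]
    mode: str

    def samples_in(self, stratum: str) -> list[str]:
        return list(self.strata.index[self.strata == stratum])


def read_gmt(path: str | Path) -> dict[str, GeneSignature]:
    """Read gene sets from a GMT file (name <tab> description <tab> genes...)."""
    signatures: dict[str, GeneSignature] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (needs >= 3 fields): {line[:80]!r}")
        name = fields[0]
        genes = tuple(g for g in fields[2:] if g)
        signatures[name] = GeneSignature(name=name, genes=genes)
    if not signatures:
        raise ValueError(f"no gene sets found in {path}")
    return signatures


def bundled_signatures() -> dict[str, GeneSignature]:
    """Gene sets shipped with the package (editable GMT under ``data/``)."""
    with resources.as_file(
        resources.files("oxystrat") / "data" / "hypoxia_signatures.gmt"
    ) as path:
        return read_gmt(path)


def _validate_expression(expr: pd.DataFrame) -> None:
    if expr.index.has_duplicates:
        raise DuplicateIdError("expression matrix has duplicate gene identifiers")
    if expr.columns.has_duplicates:
        raise DuplicateIdError("expression matrix has duplicate sample identifiers")
    values = expr.to_numpy()
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise ValueError("expression matrix contains negative values")


def score_signature(expr: pd.DataFrame, sig: GeneSignature) -> HypoxiaScores:
    """Median-split metagene score of ``sig`` for every sample of ``expr``.

    Ties at the gene median contribute -1 (a sample must be *strictly* above
    the cohort median to count as induced).
    """
    _validate_expression(expr)
    if expr.shape[1] < 2:
        raise ValueError("scoring requires at least 2 samples (cohort median)")
    present = [g for g in sig.genes if g in expr.index]
    missing = sorted(set(sig.genes) - set(present))
    if not present:
        raise SignatureOverlapError(
            f"signature {sig.name!r}: none of its {len(sig.genes)} genes "
            "are present in the expression matrix"
        )
    if missing:
        logger.warning(
            "signature %s: %d/%d genes absent from matrix and dropped: %s",
            sig.name,
            len(missing),
            len(sig.genes),
            ", ".join(missing[:10]) + ("..." if len(missing) > 10 else ""),
        )
    sub = expr.loc[present].to_numpy()
    medians = np.median(sub, axis=1, keepdims=True)
    contributions = np.where(sub > medians, 1, -1)
    scores = pd.Series(
        contributions.sum(axis=0).astype(int), index=expr.columns, name="score"
    )
    return HypoxiaScores(scores=scores, n_genes_used=len(present), signature=sig.name)


def stratify(scores: HypoxiaScores, mode: str = "tertile") -> StratumAssignment:
    """Assign hypoxia strata at score quantiles.

    Tertile mode cuts at the 1/3 and 2/3 linear-interpolation quantiles:
    ``low`` iff score <= lower cutoff, ``high`` iff score > upper cutoff,
    ``medium`` otherwise. Median mode cuts at the 50% quantile into
    ``low`` (<= median) and ``high``.
    """
    s = scores.scores
    if mode not in {"tertile", "median"}:
        raise ValueError(f"unknown stratification mode {mode!r}")
    if mode == "tertile" and len(s) < 3:
        raise ValueError("tertile stratification requires at least 3 samples")
    if len(s) < 2:
        raise ValueError("stratification requires at least 2 samples")
    if s.nunique() == 1:
        raise DegenerateScoresError(
            "score distribution is constant; strata are undefined"
        )
    values = s.to_numpy(dtype=float)
    if mode == "tertile":
        lo, hi = np.quantile(values, [1 / 3, 2 / 3])
        labels = np.where(values <= lo, "low", np.where(values > hi, "high", "medium"))
        cutoffs: tuple[float, ...] = (float(lo), float(hi))
    else:
        cut = float(np.quantile(values, 0.5))
        labels = np.where(values <= cut, "low", "high")
        cutoffs = (cut,)
    strata = pd.Series(labels, index=s.index, name="stratum")
    if mode == "median" and (strata == "high").sum() == 0:
        raise DegenerateScoresError("median split left the high stratum empty")
    return StratumAssignment(strata=strata, cutoffs=cutoffs, mode=mode)


def score_summary(scores: HypoxiaScores) -> dict[str, float]:
    """Mean, standard deviation (ddof=1 when n > 1) and median of the scores."""
    s = scores.scores.to_numpy(dtype=float)
    if len(s) == 0:
        raise ValueError("no scores to summarize")
    sd = float(np.std(s, ddof=1)) if len(s) > 1 else 0.0
    return {"mean": float(np.mean(s)), "sd": sd, "median": float(np.median(s))}
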