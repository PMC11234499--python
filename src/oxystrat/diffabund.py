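"""Differential microbe abundance between hypoxia strata, cross-cohort
concordance, and community-ecology utilities (Bray–Curtis, presence overlap).

The test is a self-contained negative-binomial Wald test on median-of-ratios
normalized counts: per taxon, group means are compared on the log2 scale and
the standard error follows from the NB variance law ``var = m + phi * m**2``
with a pooled method-of-moments dispersion. There is no shrinkage, outlier
filtering, or independent filtering; calibration is established by
simulation, and hand-auditable behavior is preferred over matching any
particular reference tool's output.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import EmptyResultError, MalformedInputError

__all__ = [
    "size_factors",
    "nb_wald",
    "concordant_microbes",
    "bray_curtis",
    "presence_overlap",
]

logger = logging.getLogger(__name__)

_LN2 = np.log(2.0)
_DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The pseudo-reference for each taxon is the geometric mean of its
    *positive* counts (zeros ignored), which keeps zero-heavy microbe
    matrices usable; each sample's factor is the median ratio of its nonzero
    counts to the reference.
    """
    values = counts.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("size factors require at least 2 samples")
    if (values < 0).any() or not np.isfinite(values).all():
        raise MalformedInputError("counts must be non-negative and finite")
    totals = values.sum(axis=0)
    dead = np.flatnonzero(totals == 0)
    if dead.size:
        names = ", ".join(map(str, counts.columns[dead][:5]))
        raise MalformedInputError(f"sample(s) with zero total counts: {names}")

    positive = values > 0
    logs = np.where(positive, np.log(np.where(positive, values, 1.0)), np.nan)
    n_pos = positive.sum(axis=1)
    log_ref = np.where(
        n_pos > 0, np.where(positive, logs, 0.0).sum(axis=1) / np.maximum(n_pos, 1), np.nan
    )  # NaN only for all-zero taxa
    usable = np.isfinite(log_ref)
    factors = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        mask = usable & (values[:, j] > 0)
        if not mask.any():
            raise MalformedInputError(
                f"sample {counts.columns[j]!r} shares no nonzero taxon with the reference"
            )
        factors[j] = np.exp(np.median(logs[mask, j] - log_ref[mask]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def nb_wald(
    counts: pd.DataFrame,
    strata: pd.Series,
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Negative-binomial Wald test of high- vs low-stratum abundance.

    ``strata`` maps sample id -> 'low'/'high' (samples in a medium stratum
    must be excluded upstream). Returns a table per tested taxon with the
    baseline normalized mean, log2 fold change (high vs low, with
    ``pseudocount`` stabilizing empty means), delta-method SE, Wald p, BH-
    adjusted p, and detection prevalence; taxa that are all-zero in both
    groups are excluded (counted in the log). Sorted by adjusted p.
    """
    strata = strata.dropna()
    levels = set(strata.unique())
    if not levels <= {"low", "high"}:
        raise ValueError(f"strata must be 'low'/'high' only; saw {sorted(levels)}")
    if levels != {"low", "high"}:
        raise ValueError("both strata must be non-empty")
    missing = [s for s in strata.index if s not in counts.columns]
    if missing:
        raise ValueError(f"strata samples absent from count matrix: {missing[:5]}")
    sub = counts[list(strata.index)]
    if factors is None:
        factors = size_factors(sub)
    y = sub.to_numpy(dtype=float) / factors.reindex(sub.columns).to_numpy()

    groups = {g: (strata == g).to_numpy() for g in ("low", "high")}
    n = {g: int(m.sum()) for g, m in groups.items()}
    mean = {g: y[:, m].mean(axis=1) for g, m in groups.items()}
    var = {
        g: y[:, m].var(axis=1, ddof=1) if n[g] > 1 else np.zeros(y.shape[0])
        for g, m in groups.items()
    }

    tested = (mean["low"] + mean["high"]) > 0
    n_dropped = int((~tested).sum())
    if n_dropped:
        logger.info("nb_wald: excluded %d taxa with all-zero counts", n_dropped)
    if not tested.any():
        raise EmptyResultError("every taxon is all-zero in both groups")

    # pooled method-of-moments dispersion: var = m + phi m^2 per group
    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    for g in ("low", "high"):
        pos = mean[g] > 0
        num[pos] += (n[g] - 1) * (var[g][pos] - mean[g][pos])
        den[pos] += (n[g] - 1) * mean[g][pos] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    phi = np.maximum(phi, _DISPERSION_FLOOR)

    log2fc = np.log2(
        (mean["high"] + pseudocount) / (mean["low"] + pseudocount)
    )
    se_sq = np.zeros(y.shape[0])
    for g in ("low", "high"):
        var_mean = (mean[g] + phi * mean[g] ** 2) / n[g]
        se_sq += var_mean / ((mean[g] + pseudocount) * _LN2) ** 2
    se = np.sqrt(se_sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "base_mean": y.mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "prevalence": (sub.to_numpy() > 0).mean(axis=1),
        },
        index=counts.index,
    ).loc[tested]
    table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table.sort_values(["p_adj", "p"]).copy()


def concordant_microbes(
    table_a: pd.DataFrame, table_b: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Taxa significant (BH-adjusted p < ``alpha``) in *both* cohorts with the
    same fold-change direction; returns their per-cohort log2FC and adjusted p."""
    shared = table_a.index.intersection(table_b.index)
    if shared.empty:
        raise EmptyResultError("the two tables share no taxa")
    a = table_a.loc[shared]
    b = table_b.loc[shared]
    hit = (
        (a["p_adj"] < alpha)
        & (b["p_adj"] < alpha)
        & (np.sign(a["log2fc"]) == np.sign(b["log2fc"]))
        & (a["log2fc"] != 0)
    )
    return pd.DataFrame(
        {
            "log2fc_a": a.loc[hit, "log2fc"],
            "log2fc_b": b.loc[hit, "log2fc"],
            "p_adj_a": a.loc[hit, "p_adj"],
            "p_adj_b": b.loc[hit, "p_adj"],
        }
    ).sort_values("p_adj_a")


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity between samples (columns).

    ``BC(i, j) = sum_t |x_ti - x_tj| / sum_t (x_ti + x_tj)``; identical
    profiles give 0, disjoint supports give 1. A pair of all-zero samples has
    no defined dissimilarity and is reported as NaN; the diagonal is 0.
    """
    x = matrix.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("Bray-Curtis requires at least 2 samples")
    if (x < 0).any() or not np.isfinite(x).all():
        raise MalformedInputError("abundances must be non-negative and finite")
    diff = np.abs(x[:, :, None] - x[:, None, :]).sum(axis=0)
    total = (x[:, :, None] + x[:, None, :]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        bc = np.where(total > 0, diff / total, np.nan)
    np.fill_diagonal(bc, 0.0)
    return pd.DataFrame(bc, index=matrix.columns, columns=matrix.columns)


def presence_overlap(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    detect_threshold: float = 0.0,
) -> dict:
    """Taxon sets detected in group A, group B, or both.

    A taxon is *present* in a group when its abundance exceeds
    ``detect_threshold`` in at least one sample of that group. Returns the
    three disjoint sets plus each set's fraction of the union.
    """
    present_a = set(matrix_a.index[(matrix_a > detect_threshold).any(axis=1)])
    present_b = set(matrix_b.index[(matrix_b > detect_threshold).any(axis=1)])
    shared = present_a & present_b
    only_a = present_a - present_b
    only_b = present_b - present_a
    union = len(shared | only_a | only_b)
    frac = (lambda s: len(s) / union if union else 0.0)
    return {
        "shared": shared,
        "a_only": only_a,
        "b_only": only_b,
        "shared_fraction": frac(shared),
        "a_only_fraction": frac(only_a),
        "b_only_fraction": frac(only_b),
    }
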