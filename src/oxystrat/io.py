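"""Readers, writers, sample alignment, run configuration, and the
end-to-end pipeline that chains scoring -> stratification -> cutoff sweep ->
survival -> differential abundance -> interaction screen.

Conventions: expression and microbe matrices are tab-separated with features
in rows (first column the gene/taxon identifier) and samples in columns; the
clinical table is a CSV with one row per sample. Sample-id matching is exact
string equality — no trimming or case folding — because silent identifier
munging is a classic cohort-join bug. Output tables carry a leading comment
line naming the generating stage and its parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import scoring, survival, sweep, diffabund
from .exceptions import (
    AlignmentError,
    DuplicateIdError,
    MalformedInputError,
    PipelineError,
)

__all__ = [
    "read_expression",
    "read_microbes",
    "read_clinical",
    "read_truth",
    "write_table",
    "RunConfig",
    "CohortBundle",
    "load_bundle",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_SAMPLE_HEADER_HINTS = {"sample", "sample_id", "samples", "sampleid"}


def _read_matrix(path: str | Path, kind: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise MalformedInputError(f"cannot parse {kind} matrix {path}: {exc}") from exc
    index_name = (df.index.name or "").strip().lower()
    if index_name in _SAMPLE_HEADER_HINTS:
        raise MalformedInputError(
            f"{kind} matrix {path} appears transposed (first column {df.index.name!r} "
            "names samples); provide features in rows and samples in columns"
        )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()[:5]
        raise DuplicateIdError(f"{kind} matrix {path}: duplicate feature ids {list(dups)}")
    if df.columns.has_duplicates:
        raise DuplicateIdError(f"{kind} matrix {path}: duplicate sample ids")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise MalformedInputError(f"{kind} matrix {path}: non-numeric entries: {exc}") from exc
    if not np.isfinite(values).all() or (values < 0).any():
        raise MalformedInputError(
            f"{kind} matrix {path}: values must be finite and non-negative"
        )
    return df.astype(float)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (TPM-like values)."""
    return _read_matrix(path, "expression")


def read_microbes(path: str | Path) -> pd.DataFrame:
    """Read a taxa x samples microbe abundance TSV."""
    return _read_matrix(path, "microbe")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical CSV (sample_id, os_time, os_event, covariates...)."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in ("sample_id", "os_time", "os_event"):
        if col not in df.columns:
            raise MalformedInputError(f"clinical table {path} lacks column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].unique()[:5]
        raise DuplicateIdError(f"clinical table {path}: duplicate sample ids {list(dups)}")
    for col in ("os_time", "os_event"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError) as exc:
            raise MalformedInputError(
                f"clinical table {path}: column {col!r} is not numeric: {exc}"
            ) from exc
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_table(
    df: pd.DataFrame, path: str | Path, stage: str, params: dict | None = None, **to_csv
) -> Path:
    """Write a TSV/CSV with a leading comment naming the generating stage."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    params = params or {}
    header = "# oxystrat stage=" + stage
    if params:
        header += " " + " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep=sep, **to_csv)
    return path


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (loadable from YAML)."""

    expression: Path
    clinical: Path
    microbes: Path
    signatures: list[str] = field(default_factory=lambda: ["BUFFA_HYPOXIA"])
    gmt: Path | None = None
    stratify_mode: str = "tertile"
    grid_lo: int = 10
    grid_hi: int = 90
    sweep_alpha: float = 0.05
    prevalence_min: float = 0.10
    diffabund_alpha: float = 0.05
    screen_encoding: str = "presence"
    seed: int = 0

    def __post_init__(self):
        for name in ("expression", "clinical", "microbes"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.gmt is not None:
            self.gmt = Path(self.gmt)
            if not self.gmt.exists():
                raise FileNotFoundError(f"GMT file not found: {self.gmt}")
        if self.stratify_mode not in {"tertile", "median"}:
            raise ValueError(f"unknown stratify_mode {self.stratify_mode!r}")
        if not 0 <= self.prevalence_min < 1:
            raise ValueError("prevalence_min must lie in [0, 1)")
        for name in ("sweep_alpha", "diffabund_alpha"):
            a = float(getattr(self, name))
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not self.signatures:
            raise ValueError("at least one signature name is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolve_signatures(self) -> list[scoring.GeneSignature]:
        available = scoring.bundled_signatures()
        if self.gmt is not None:
            available.update(scoring.read_gmt(self.gmt))
        missing = [s for s in self.signatures if s not in available]
        if missing:
            raise ValueError(
                f"signatures not found in bundled or supplied GMT: {missing}; "
                f"available: {sorted(available)}"
            )
        return [available[s] for s in self.signatures]


@dataclass
class CohortBundle:
    """Sample-aligned expression + clinical + microbe data, the unit every
    downstream stage consumes; ``dropped`` reports per-source discards."""

    expression: pd.DataFrame
    clinical: pd.DataFrame
    microbes: pd.DataFrame
    dropped: dict[str, list[str]]
    scores: scoring.HypoxiaScores | None = None
    strata: scoring.StratumAssignment | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.clinical["sample_id"])


def load_bundle(
    expression: str | Path | pd.DataFrame,
    clinical: str | Path | pd.DataFrame,
    microbes: str | Path | pd.DataFrame,
) -> CohortBundle:
    """Load the three sources and align them on the intersection of sample
    ids, preserving clinical-table order; per-source drops are reported."""
    expr = expression if isinstance(expression, pd.DataFrame) else read_expression(expression)
    clin = clinical if isinstance(clinical, pd.DataFrame) else read_clinical(clinical)
    micro = microbes if isinstance(microbes, pd.DataFrame) else read_microbes(microbes)

    clin_ids = list(clin["sample_id"].astype(str))
    expr_ids = set(map(str, expr.columns))
    micro_ids = set(map(str, micro.columns))
    shared = [s for s in clin_ids if s in expr_ids and s in micro_ids]
    if not shared:
        raise AlignmentError(
            "no sample id is shared by the expression, clinical and microbe sources"
        )
    dropped = {
        "clinical": [s for s in clin_ids if s not in shared],
        "expression": sorted(expr_ids - set(shared)),
        "microbes": sorted(micro_ids - set(shared)),
    }
    for source, ids in dropped.items():
        if ids:
            logger.info("load_bundle: dropped %d unmatched ids from %s", len(ids), source)
    return CohortBundle(
        expression=expr[shared].copy(),
        clinical=clin.set_index("sample_id").loc[shared].reset_index(),
        microbes=micro[shared].copy(),
        dropped=dropped,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full analysis and write every intermediate table plus a
    machine-readable manifest. Returns the output directory.

    Stages: score each signature -> stratify the primary (first) signature ->
    percentile sweep per signature (ranked by significance area) -> KM /
    log-rank / Cox on the high-vs-low strata -> NB differential abundance ->
    microbe-by-hypoxia interaction screen.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        bundle = load_bundle(config.expression, config.clinical, config.microbes)
        signatures = config.resolve_signatures()

        stage = "score"
        surv = survival.SurvivalData.from_clinical(bundle.clinical)
        all_scores: dict[str, scoring.HypoxiaScores] = {}
        for sig in signatures:
            sc = scoring.score_signature(bundle.expression, sig)
            all_scores[sig.name] = sc
            write_table(
                sc.to_frame(),
                outdir / f"scores_{sig.name}.tsv",
                "score",
                {"signature": sig.name, "genes_used": sc.n_genes_used},
                index=False,
            )
        primary = all_scores[signatures[0].name]
        bundle.scores = primary

        stage = "stratify"
        strata = scoring.stratify(primary, mode=config.stratify_mode)
        bundle.strata = strata
        write_table(
            strata.strata.rename_axis("sample_id").to_frame(),
            outdir / "strata.tsv",
            "stratify",
            {"mode": strata.mode, "cutoffs": ",".join(f"{c:g}" for c in strata.cutoffs)},
        )

        stage = "sweep"
        areas = {}
        for name, sc in all_scores.items():
            curve = sweep.pvalue_curve(
                sc,
                surv,
                grid_lo=config.grid_lo,
                grid_hi=config.grid_hi,
                alpha=config.sweep_alpha,
            )
            areas[name] = curve.area
            write_table(
                curve.table,
                outdir / f"sweep_{name}.tsv",
                "sweep",
                {"signature": name, "alpha": config.sweep_alpha, "area": curve.area},
            )
        ranking = pd.DataFrame(
            sorted(areas.items(), key=lambda kv: (-(kv[1] or 0.0), kv[0])),
            columns=["signature", "area"],
        )
        write_table(ranking, outdir / "signature_ranking.tsv", "sweep", index=False)

        stage = "survival"
        hilo = strata.strata[strata.strata.isin(["low", "high"])]
        surv_hilo = survival.SurvivalData(
            table=surv.table.loc[hilo.index]
        )
        km = survival.km_estimate(surv_hilo, hilo)
        write_table(km["risk_table"], outdir / "km_risk_table.tsv", "km")
        lr = survival.logrank_test(surv_hilo, hilo)
        cox_table = surv_hilo.table.copy()
        cox_table["hypoxia_high"] = (hilo == "high").astype(float)
        cox = survival.cox_fit(survival.SurvivalData(table=cox_table), ["hypoxia_high"])
        write_table(cox.summary, outdir / "cox_hypoxia.tsv", "cox")
        with open(outdir / "survival_tests.json", "w") as fh:
            json.dump(
                {
                    "logrank": lr,
                    "cox_hypoxia_p": cox.p("hypoxia_high"),
                    "cox_hypoxia_hr": float(cox.summary.loc["hypoxia_high", "hr"]),
                    "n": cox.n,
                    "n_events": cox.n_events,
                },
                fh,
                indent=1,
            )

        stage = "diffabund"
        da = diffabund.nb_wald(bundle.microbes, hilo)
        write_table(da, outdir / "diffabund.tsv", "diffabund",
                    {"alpha": config.diffabund_alpha})

        stage = "interaction_screen"
        screen = survival.interaction_screen(
            bundle.microbes,
            hilo,
            surv_hilo,
            prevalence_min=config.prevalence_min,
            encoding=config.screen_encoding,
        )
        write_table(
            screen,
            outdir / "interaction_screen.tsv",
            "interaction_screen",
            {"prevalence_min": config.prevalence_min, "encoding": config.screen_encoding},
        )

        stage = "manifest"
        from . import __version__

        manifest = {
            "package": {"name": "oxystrat", "version": __version__},
            "config": {
                k: (str(v) if isinstance(v, Path) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            "seed": config.seed,
            "inputs": {
                name: {"path": str(p), "sha256": _sha256(Path(p))}
                for name, p in (
                    ("expression", config.expression),
                    ("clinical", config.clinical),
                    ("microbes", config.microbes),
                )
            },
            "n_samples": len(bundle.sample_ids),
            "dropped": bundle.dropped,
            "signature_areas": areas,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return outdir
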