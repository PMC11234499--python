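"""Table-one style cohort comparisons.

Categorical variables are compared across groups with the Pearson chi-square
test of independence (Yates continuity correction optional and only
meaningful for 2x2 tables); continuous variables with equal-variance one-way
ANOVA. The ANOVA can be reconstructed exactly from per-group summary
statistics (mean, SD, n), which makes published summary tables re-checkable
without the raw data:

    SSB = sum n_i (xbar_i - xbar)^2,  SSW = sum (n_i - 1) s_i^2,
    F = [SSB / (k - 1)] / [SSW / (N - k)].

For two groups this is the pooled-variance two-sample t-test squared.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["chisq_independence", "anova_oneway_from_summary", "build_table_one"]


def chisq_independence(table, yates: bool = False) -> dict:
    """Pearson chi-square test of independence on an r x c count table.

    ``yates`` requests the continuity correction, which is applied only when
    the table is 2x2 (df = 1), matching standard practice. Returns the
    statistic, degrees of freedom, and upper-tail p.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any() or not np.isfinite(t).all():
        raise ValueError("counts must be non-negative and finite")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row or column marginal; drop the empty category first")
    stat, p, df, _ = stats.chi2_contingency(t, correction=yates)
    return {"chi_square": float(stat), "df": int(df), "p": float(p)}


def anova_oneway_from_summary(means, sds, ns) -> dict:
    """Equal-variance one-way ANOVA reconstructed from per-group summaries.

    Equals one-way ANOVA on the raw data when the summaries were computed
    from it (sample SD, ddof=1). A zero within-group sum of squares with
    nonzero between-group spread yields an explicit infinite F (p = 0).
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if not (means.shape == sds.shape == ns.shape) or means.ndim != 1:
        raise ValueError("means, sds, ns must be 1-D arrays of equal length")
    k = len(means)
    if k < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2")
    if (sds < 0).any():
        raise ValueError("standard deviations must be non-negative")
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df1, df2 = k - 1, int(n_total) - k
    if ssw == 0.0:
        if ssb == 0.0:
            return {"F": 0.0, "df1": df1, "df2": df2, "p": 1.0}
        return {"F": float("inf"), "df1": df1, "df2": df2, "p": 0.0}
    f = (ssb / df1) / (ssw / df2)
    return {"F": float(f), "df1": df1, "df2": df2, "p": float(stats.f.sf(f, df1, df2))}


def _is_continuous(series: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(series) and series.nunique(dropna=True) > 2


def build_table_one(
    clinical: pd.DataFrame,
    grouping: str,
    exclude: tuple[str, ...] = ("sample_id",),
    yates_2x2: bool = True,
) -> pd.DataFrame:
    """Per-variable group comparison table (counts/percent or mean/SD + p).

    Missing values in categorical variables are kept as an explicit
    ``Unknown`` category. Variables with a single observed level get no p
    (with a note). Continuous variables use the summary-ANOVA above;
    categorical variables use Pearson chi-square (Yates on 2x2 tables by
    default, mirroring common statistical software).
    """
    if grouping not in clinical.columns:
        raise ValueError(f"grouping column {grouping!r} not in clinical table")
    group = clinical[grouping].astype(str).fillna("Unknown")
    group_levels = list(pd.unique(group))
    rows: list[dict] = []
    rows.append(
        {
            "variable": "n",
            "level": "",
            **{g: str(int((group == g).sum())) for g in group_levels},
            "p": np.nan,
            "note": "",
        }
    )
    for col in clinical.columns:
        if col == grouping or col in exclude:
            continue
        series = clinical[col]
        if _is_continuous(series):
            means, sds, ns = [], [], []
            cells = {}
            for g in group_levels:
                vals = series[group == g].dropna().to_numpy(dtype=float)
                if len(vals) >= 2:
                    means.append(vals.mean())
                    sds.append(vals.std(ddof=1))
                    ns.append(len(vals))
                cells[g] = (
                    f"{vals.mean():.2f} ({vals.std(ddof=1):.2f})" if len(vals) else ""
                )
            note, p = "", np.nan
            if len(means) >= 2 and max(sds) > 0:
                p = anova_oneway_from_summary(means, sds, ns)["p"]
            elif len(means) >= 2:
                note = "constant within groups; p omitted"
            else:
                note = "insufficient data; p omitted"
            rows.append(
                {
                    "variable": f"{col} [mean (SD)]",
                    "level": "",
                    **cells,
                    "p": p,
                    "note": note,
                }
            )
        else:
            cat = series.astype("object").where(series.notna(), "Unknown").astype(str)
            crosstab = pd.crosstab(cat, group).reindex(columns=group_levels, fill_value=0)
            note, p = "", np.nan
            if crosstab.shape[0] < 2:
                note = "single level; p omitted"
            else:
                nonzero = crosstab.loc[:, crosstab.sum(axis=0) > 0]
                try:
                    p = chisq_independence(nonzero.to_numpy(), yates=yates_2x2)["p"]
                except ValueError as exc:
                    note = f"test unavailable: {exc}"
            rows.append(
                {"variable": f"{col} (%)", "level": "", **{g: "" for g in group_levels},
                 "p": p, "note": note}
            )
            group_sizes = {g: int((group == g).sum()) for g in group_levels}
            for level in crosstab.index:
                rows.append(
                    {
                        "variable": f"{col} (%)",
                        "level": str(level),
                        **{
                            g: f"{crosstab.loc[level, g]} "
                            f"({100 * crosstab.loc[level, g] / group_sizes[g]:.1f})"
                            for g in group_levels
                        },
                        "p": np.nan,
                        "note": "",
                    }
                )
    return pd.DataFrame(rows, columns=["variable", "level", *group_levels, "p", "note"])
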