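"""NB Wald differential abundance, normalization, concordance, ecology."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from oxystrat import (
    bray_curtis,
    concordant_microbes,
    nb_wald,
    presence_overlap,
    size_factors,
)
from oxystrat.exceptions import EmptyResultError, MalformedInputError


def _counts(values, taxa=None, samples=None):
    values = np.asarray(values, dtype=float)
    taxa = taxa or [f"t{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=taxa, columns=samples)


# -- size factors -----------------------------------------------------------


def test_identical_columns_get_unit_factors():
    c = _counts([[4, 4], [7, 7], [1, 1]])
    np.testing.assert_allclose(size_factors(c), [1.0, 1.0])


def test_doubled_column_ratio_arithmetic():
    c = _counts([[2, 4], [10, 20], [7, 14]])
    np.testing.assert_allclose(
        size_factors(c), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
    )


def test_factors_scale_equivariant(rng):
    c = _counts(rng.poisson(30, size=(20, 6)) + 1)
    a = size_factors(c)
    b = size_factors(c * 10)
    np.testing.assert_allclose(a / a.iloc[0], b / b.iloc[0], rtol=1e-12)


def test_zero_total_sample_is_named():
    c = _counts([[1, 0], [2, 0]])
    with pytest.raises(MalformedInputError, match="s1"):
        size_factors(c)


def test_size_factors_match_deseq2_on_dense_counts(rng):
    """Independent cross-check: on a dense matrix the median-of-ratios
    factors agree with pydeseq2's, up to the geometric-mean rescaling."""
    pydeseq2_dds = pytest.importorskip("pydeseq2.dds")
    counts = rng.poisson(rng.uniform(5, 200, size=(40, 1)), size=(40, 8)) + 1
    c = _counts(counts)
    mine = size_factors(c).to_numpy()
    meta = pd.DataFrame({"cond": ["a"] * 4 + ["b"] * 4}, index=c.columns)
    dds = pydeseq2_dds.DeseqDataSet(
        counts=c.T.astype(int), metadata=meta, design="~cond", quiet=True
    )
    dds.fit_size_factors()
    ref = np.asarray(dds.obs["size_factors"], dtype=float)
    ref = ref / np.exp(np.mean(np.log(ref)))
    np.testing.assert_allclose(mine, ref, rtol=1e-6)


# -- NB Wald ----------------------------------------------------------------


def _strata(n_low, n_high, samples):
    return pd.Series(["low"] * n_low + ["high"] * n_high, index=samples)


def test_identical_groups_are_exactly_null(rng):
    base = rng.negative_binomial(2, 2 / (2 + 30), size=(15, 40))
    c = _counts(np.hstack([base, base]))
    table = nb_wald(c, _strata(40, 40, c.columns))
    np.testing.assert_allclose(table["log2fc"], 0.0, atol=1e-12)
    assert (table["p"] == 1.0).all()


def test_label_swap_negates_log2fc(rng):
    counts = rng.negative_binomial(2, 2 / (2 + 25), size=(20, 60))
    c = _counts(counts)
    s = _strata(30, 30, c.columns)
    swapped = s.map({"low": "high", "high": "low"})
    a = nb_wald(c, s).sort_index()
    b = nb_wald(c, swapped).sort_index()
    np.testing.assert_allclose(a["log2fc"], -b["log2fc"], atol=1e-10)
    np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)


def test_all_zero_taxa_excluded(rng):
    counts = rng.poisson(20, size=(5, 20)).astype(float)
    counts[2] = 0.0
    c = _counts(counts)
    table = nb_wald(c, _strata(10, 10, c.columns))
    assert "t2" not in table.index
    assert len(table) == 4


def test_bh_adjustment_is_monotone(rng):
    counts = rng.negative_binomial(2, 2 / (2 + 25), size=(50, 60))
    table = nb_wald(_counts(counts), _strata(30, 30, [f"s{j}" for j in range(60)]))
    by_p = table.sort_values("p")
    assert by_p["p_adj"].is_monotonic_increasing
    assert (table["p_adj"] >= table["p"] - 1e-15).all()


def test_log2fc_matches_plain_ratio_at_large_means(rng):
    m_low, m_high = 500.0, 2000.0
    r = 10.0
    low = rng.negative_binomial(r, r / (r + m_low), size=(1, 200))
    high = rng.negative_binomial(r, r / (r + m_high), size=(1, 200))
    c = _counts(np.hstack([low, high]))
    table = nb_wald(
        c, _strata(200, 200, c.columns), factors=pd.Series(1.0, index=c.columns)
    )
    plain = np.log2(high.mean() / low.mean())
    assert table["log2fc"].iloc[0] == pytest.approx(plain, abs=0.01)


def test_nb_wald_recovers_fourfold_change(rng):
    """True high/low mean ratio 4 => log2FC near 2 (100 samples per arm)."""
    estimates = []
    for rep in range(10):
        r = np.random.default_rng(300 + rep)
        phi = 0.5
        k = 1 / phi
        low = r.negative_binomial(k, k / (k + 50), size=(1, 100))
        high = r.negative_binomial(k, k / (k + 200), size=(1, 100))
        c = _counts(np.hstack([low, high]))
        table = nb_wald(
            c, _strata(100, 100, c.columns), factors=pd.Series(1.0, index=c.columns)
        )
        estimates.append(table["log2fc"].iloc[0])
    assert np.mean(estimates) == pytest.approx(2.0, abs=0.3)


def test_medium_stratum_must_be_excluded_upstream():
    c = _counts([[1, 2, 3]])
    s = pd.Series(["low", "medium", "high"], index=c.columns)
    with pytest.raises(ValueError, match="low.*high|high.*low"):
        nb_wald(c, s)


# -- concordance ------------------------------------------------------------


def test_concordance_requires_sign_agreement():
    a = pd.DataFrame({"log2fc": [2.0], "p_adj": [0.01]}, index=["tx"])
    b = pd.DataFrame({"log2fc": [-2.0], "p_adj": [0.01]}, index=["tx"])
    assert len(concordant_microbes(a, b)) == 0


def test_concordance_includes_weak_but_significant_agreement():
    a = pd.DataFrame({"log2fc": [2.0], "p_adj": [0.01]}, index=["tx"])
    b = pd.DataFrame({"log2fc": [0.5], "p_adj": [0.04]}, index=["tx"])
    result = concordant_microbes(a, b)
    assert list(result.index) == ["tx"]
    assert result.loc["tx", "log2fc_b"] == 0.5


def test_concordance_empty_intersection_is_explicit():
    a = pd.DataFrame({"log2fc": [1.0], "p_adj": [0.01]}, index=["t1"])
    b = pd.DataFrame({"log2fc": [1.0], "p_adj": [0.01]}, index=["t2"])
    with pytest.raises(EmptyResultError):
        concordant_microbes(a, b)


# -- ecology utilities ------------------------------------------------------


def test_bray_curtis_hand_cases():
    c = _counts([[1, 2, 0], [2, 1, 4]])
    bc = bray_curtis(c)
    assert bc.loc["s0", "s1"] == pytest.approx(1 / 3)
    assert bc.loc["s0", "s0"] == 0.0
    # disjoint supports
    d = _counts([[3, 0], [0, 5]])
    assert bray_curtis(d).loc["s0", "s1"] == 1.0


def test_bray_curtis_properties(rng):
    c = _counts(rng.poisson(8, size=(12, 5)))
    bc = bray_curtis(c)
    assert np.allclose(bc, bc.T)
    assert ((bc.to_numpy() >= 0) & (bc.to_numpy() <= 1)).all()
    shuffled = bray_curtis(c.sample(frac=1.0, random_state=1))
    np.testing.assert_allclose(bc.to_numpy(), shuffled.to_numpy())
    ref = squareform(pdist(c.T.to_numpy(), metric="braycurtis"))
    np.testing.assert_allclose(bc.to_numpy(), ref, atol=1e-12)


def test_bray_curtis_all_zero_pair_is_missing():
    c = _counts([[0, 0, 1], [0, 0, 2]])
    bc = bray_curtis(c)
    assert np.isnan(bc.loc["s0", "s1"])
    assert bc.loc["s0", "s0"] == 0.0
    assert bc.loc["s0", "s2"] == 1.0


def test_presence_overlap_set_arithmetic():
    a = _counts([[1, 0], [2, 1], [3, 3], [0, 0]], taxa=list("wxyz"))
    b = _counts([[0, 0], [5, 0], [1, 0], [2, 2]], taxa=list("wxyz"))
    res = presence_overlap(a, b)
    assert res["shared"] == {"x", "y"}
    assert res["a_only"] == {"w"}
    assert res["b_only"] == {"z"}
    assert res["shared_fraction"] == pytest.approx(0.5)


def test_presence_overlap_identical_and_disjoint():
    a = _counts([[1, 2], [3, 4]])
    assert presence_overlap(a, a)["shared_fraction"] == 1.0
    b = _counts([[0, 0], [3, 4]])
    c = _counts([[1, 2], [0, 0]])
    res = presence_overlap(b, c)
    assert res["shared"] == set()
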