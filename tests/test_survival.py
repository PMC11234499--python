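"""Kaplan–Meier, log-rank, Breslow Cox fits, and the interaction screen.

The Cox solver is validated against a frozen R ``survival::coxph``
(ties="breslow") result on a heavily tied dataset and against lifelines on
tie-free data (where Breslow and Efron coincide).
"""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from oxystrat import (
    SimulationConfig,
    SurvivalData,
    cox_fit,
    interaction_screen,
    km_estimate,
    logrank_test,
    simulate_cohort,
)
from oxystrat.exceptions import ConvergenceError, EmptyResultError, RankDeficiencyError


def _surv(time, event, **cov):
    n = len(time)
    df = pd.DataFrame({"os_time": time, "os_event": event, **cov},
                      index=[f"s{i}" for i in range(n)])
    return SurvivalData(table=df)


# -- Kaplan-Meier -----------------------------------------------------------


def test_km_hand_product_limit(km_hand_data):
    data = SurvivalData.from_clinical(km_hand_data)
    group = pd.Series("all", index=data.sample_ids)
    res = km_estimate(data, group, risk_times=[0, 1, 2, 3])
    curve = res["curves"]["all"].set_index("time")["survival"]
    assert curve.loc[1.0] == pytest.approx(2 / 3)
    assert curve.loc[2.0] == pytest.approx(1 / 3)
    assert curve.loc[3.0] == pytest.approx(1 / 3)
    assert list(res["risk_table"]["all"]) == [3, 3, 2, 1]


def test_km_no_events_is_flat_one():
    data = _surv([1.0, 2.0, 3.0], [0, 0, 0])
    res = km_estimate(data, pd.Series("g", index=data.sample_ids))
    assert (res["curves"]["g"]["survival"] == 1.0).all()


def test_km_missing_group_label_rejected(km_hand_data):
    data = SurvivalData.from_clinical(km_hand_data)
    partial = pd.Series({"a": "g"})  # b, c unlabeled
    with pytest.raises(ValueError, match="missing"):
        km_estimate(data, partial)


def test_km_equals_empirical_survival_without_censoring(rng):
    t = rng.exponential(1.0, 200)
    data = _surv(t, np.ones(200, dtype=int))
    res = km_estimate(data, pd.Series("g", index=data.sample_ids))
    curve = res["curves"]["g"]
    emp = [(t > x).mean() for x in curve["time"]]
    np.testing.assert_allclose(curve["survival"], emp, atol=1e-12)
    assert (np.diff(curve["survival"]) <= 1e-12).all()


# -- log-rank ---------------------------------------------------------------


def test_logrank_on_identical_groups_is_null():
    t = [1.0, 2.0, 3.0, 4.0]
    e = [1, 0, 1, 1]
    data = _surv(t + t, e + e)
    group = pd.Series(["A"] * 4 + ["B"] * 4, index=data.sample_ids)
    res = logrank_test(data, group)
    assert res["chi_square"] == pytest.approx(0.0, abs=1e-12)
    assert res["p"] == pytest.approx(1.0)
    assert res["df"] == 1


def test_logrank_requires_two_groups(km_hand_data):
    data = SurvivalData.from_clinical(km_hand_data)
    with pytest.raises(ValueError, match="2 groups"):
        logrank_test(data, pd.Series("g", index=data.sample_ids))


def test_logrank_detects_strong_hazard_difference():
    cfg = SimulationConfig(n_samples=300, n_genes=4, n_signature_genes=2,
                           n_taxa=3, n_hypoxia_taxa=0, hypoxia_log_hr=1.0, seed=3)
    c = simulate_cohort(cfg)
    h = np.array([c.truth["h"][s] for s in c.sample_ids])
    group = pd.Series(np.where(h > np.median(h), "high", "low"),
                      index=pd.Index(c.sample_ids))
    res = logrank_test(SurvivalData.from_clinical(c.clinical), group)
    assert res["p"] < 1e-4


def test_logrank_agrees_with_univariate_cox_wald_at_large_n():
    cfg = SimulationConfig(n_samples=2000, n_genes=4, n_signature_genes=2,
                           n_taxa=3, n_hypoxia_taxa=0, hypoxia_log_hr=0.15, seed=8)
    c = simulate_cohort(cfg)
    h = np.array([c.truth["h"][s] for s in c.sample_ids])
    high = (h > np.median(h)).astype(float)
    data = SurvivalData.from_clinical(c.clinical)
    lr = logrank_test(data, pd.Series(np.where(high == 1, "high", "low"),
                                      index=data.sample_ids))
    table = data.table.copy()
    table["high"] = high
    cox = cox_fit(SurvivalData(table=table), ["high"])
    z_lr = np.sqrt(lr["chi_square"])
    z_cox = abs(cox.summary.loc["high", "z"])
    assert z_lr == pytest.approx(z_cox, rel=0.05)


# -- Cox fits ---------------------------------------------------------------


def test_cox_matches_frozen_r_breslow_on_heavy_ties():
    # survival::coxph(Surv(t,e)~x, ties="breslow") on this dataset gives
    # coef 0.1791047814, se 0.6351245709, p 0.7779439299
    t = [1, 1, 1, 1, 2, 2, 2, 3, 3, 4, 5, 5, 6, 7]
    e = [1, 1, 1, 0, 1, 1, 0, 1, 1, 1, 0, 1, 1, 0]
    x = [1, 1, 0, 1, 0, 1, 0, 1, 0, 0, 1, 0, 1, 0]
    res = cox_fit(_surv(t, e, x=x), ["x"])
    assert res.coef("x") == pytest.approx(0.1791047814, abs=1e-8)
    assert res.summary.loc["x", "se"] == pytest.approx(0.6351245709, abs=1e-8)
    assert res.p("x") == pytest.approx(0.7779439299, abs=1e-8)
    assert res.n == 14 and res.n_events == 10


def test_cox_agrees_with_lifelines_on_tie_free_data(rng):
    n = 250
    x1 = rng.binomial(1, 0.5, n).astype(float)
    x2 = rng.normal(size=n)
    t = rng.exponential(1 / np.exp(0.7 * x1 - 0.4 * x2))
    horizon = np.quantile(t, 0.8)
    e = (t <= horizon).astype(int)
    t = np.minimum(t, horizon)
    mine = cox_fit(_surv(t, e, x1=x1, x2=x2), ["x1", "x2"])
    df = pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2})
    ref = CoxPHFitter().fit(df, "t", "e", formula="x1 + x2")
    np.testing.assert_allclose(
        mine.summary["coef"].to_numpy(), ref.params_.to_numpy(), atol=1e-5
    )
    np.testing.assert_allclose(
        mine.summary["se"].to_numpy(), ref.standard_errors_.to_numpy(), atol=1e-5
    )


def test_cox_binary_label_swap_flips_sign(rng):
    n = 120
    x = rng.binomial(1, 0.5, n).astype(float)
    t = rng.exponential(1 / np.exp(0.8 * x))
    e = np.ones(n, dtype=int)
    a = cox_fit(_surv(t, e, x=x), ["x"])
    b = cox_fit(_surv(t, e, x=1.0 - x), ["x"])
    assert a.coef("x") == pytest.approx(-b.coef("x"), abs=1e-7)
    assert a.p("x") == pytest.approx(b.p("x"), abs=1e-9)


def test_cox_result_invariants(rng):
    n = 100
    x = rng.normal(size=n)
    t = rng.exponential(1 / np.exp(0.5 * x))
    res = cox_fit(_surv(t, np.ones(n, dtype=int), x=x), ["x"])
    row = res.summary.loc["x"]
    assert row["hr"] == pytest.approx(np.exp(row["coef"]))
    assert row["hr_lower95"] < row["hr"] < row["hr_upper95"]
    assert 0 < row["p"] <= 1


def test_cox_constant_covariate_is_rank_deficient():
    with pytest.raises(RankDeficiencyError):
        cox_fit(_surv([1, 2, 3, 4], [1, 1, 1, 0], x=[2, 2, 2, 2]), ["x"])


def test_cox_separation_raises_convergence_error():
    # all x=1 subjects fail before any x=0 subject: monotone likelihood
    t = [1, 2, 3, 4, 5, 6, 7, 8]
    e = [1, 1, 1, 1, 1, 1, 1, 1]
    x = [1, 1, 1, 1, 0, 0, 0, 0]
    with pytest.raises(ConvergenceError):
        cox_fit(_surv(t, e, x=x), ["x"])


def test_cox_loghr_recovery():
    est = []
    for rep in range(5):
        r = np.random.default_rng(900 + rep)
        n = 2000
        x = r.binomial(1, 0.5, n).astype(float)
        t = r.exponential(1 / (0.1 * np.exp(0.7 * x)))
        horizon = 30.0
        e = (t <= horizon).astype(int)
        t = np.minimum(t, horizon)
        est.append(cox_fit(_surv(t, e, x=x), ["x"]).coef("x"))
    assert np.mean(est) == pytest.approx(0.7, abs=0.08)


# -- interaction screen -----------------------------------------------------


def _screen_inputs(n=200, n_taxa=12, gamma_x=0.0, seed=0):
    r = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    hyp = pd.Series(r.binomial(1, 0.5, n).astype(float), index=ids)
    # half the taxa sparse (~55% prevalence), half dense, so presence coding
    # is informative for the planted taxon t0
    means = np.where(np.arange(n_taxa) % 2 == 0, 1.0, 20.0)
    counts = r.negative_binomial(2, 2 / (2 + means[:, None]), size=(n_taxa, n))
    microbes = pd.DataFrame(counts, index=[f"t{j}" for j in range(n_taxa)], columns=ids)
    present = (microbes.iloc[0] > 0).to_numpy(dtype=float)
    eta = 0.5 * hyp.to_numpy() + gamma_x * hyp.to_numpy() * present
    t = r.exponential(1 / (0.1 * np.exp(eta)))
    horizon = 25.0
    e = (t <= horizon).astype(int)
    t = np.minimum(t, horizon)
    data = SurvivalData(table=pd.DataFrame(
        {"os_time": t, "os_event": e}, index=ids))
    return microbes, hyp, data


def test_screen_prevalence_filter_excludes_rare_taxa():
    microbes, hyp, data = _screen_inputs(seed=1)
    rare = pd.Series(0.0, index=microbes.columns)
    rare.iloc[:4] = 5.0  # 2% prevalence
    microbes = pd.concat([microbes, rare.to_frame("rare").T])
    table = interaction_screen(microbes, hyp, data, prevalence_min=0.10)
    assert "rare" not in table.index
    assert (table["prevalence"] >= 0.10).all()


def test_screen_reports_bh_adjusted_interaction_terms():
    microbes, hyp, data = _screen_inputs(seed=2)
    table = interaction_screen(microbes, hyp, data)
    assert {"coef_interaction", "p", "p_adj", "prevalence"} <= set(table.columns)
    assert (table["p_adj"] >= table["p"] - 1e-12).all()
    assert table["p_adj"].is_monotonic_increasing
    np.testing.assert_allclose(
        table["hr_interaction"], np.exp(table["coef_interaction"])
    )


def test_screen_accepts_low_high_labels():
    microbes, hyp, data = _screen_inputs(seed=3)
    labels = pd.Series(np.where(hyp > 0, "high", "low"), index=hyp.index)
    a = interaction_screen(microbes, hyp, data)
    b = interaction_screen(microbes, labels, data)
    pd.testing.assert_frame_equal(a, b)


def test_screen_empty_after_filter_is_explicit():
    microbes, hyp, data = _screen_inputs(seed=4)
    with pytest.raises(EmptyResultError):
        interaction_screen(microbes * 0.0, hyp, data, prevalence_min=0.10)


def test_screen_detects_planted_interaction():
    hits = 0
    for rep in range(5):
        microbes, hyp, data = _screen_inputs(n=400, gamma_x=1.5, seed=50 + rep)
        table = interaction_screen(microbes, hyp, data)
        hits += table.loc["t0", "p_adj"] < 0.05
    assert hits >= 4
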