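# Methods

This note documents the models, conventions and design choices behind
`oxystrat`, in the spirit of a statistical methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Hypoxia metagene score

For a signature of G genes found in the matrix, sample *i* receives
`score_i = Σ_g s_gi` with `s_gi = +1` if expression of gene g in sample i is
*strictly* greater than g's across-cohort median and −1 otherwise. The score
is an integer in [−G, +G] with the parity of G.

Choices and their reasons:

* **Median-split rule for every signature.** The same +1/−1 rule is applied
  to any gene list (the bundled Buffa-style 52-gene hypoxia metagene, or any
  user GMT). Published cohort summaries of this score (means near 8–15 with
  SDs of 14–25 on a ±52 scale) are consistent with this integer rule.
  Alternative per-gene z-score averaging is deliberately out of scope: the
  median split is rank-based and therefore insensitive to the expression
  unit (TPM, FPKM, log-TPM), which matters when cohorts are processed by
  different centers.
* **Ties score −1.** Deterministic and conservative; ties are essentially
  absent on continuous expression but common in degenerate test fixtures.
* **Missing signature genes** are dropped from G with a logged warning, never
  imputed.
* **Stratification** uses linear-interpolation quantiles (numpy default) at
  1/3 and 2/3 (or 1/2). Boundary rule: `low` iff score ≤ lower cutoff,
  `high` iff score > upper cutoff. This makes the three strata a partition —
  a sample can never satisfy two rules — and yields group sizes {333, 334}
  on 1,000 distinct scores. A constant score vector is a hard error
  (`DegenerateScoresError`) rather than an arbitrary assignment.
* The bundled gene list ships as an editable GMT; signatures are
  configuration, not code.

## Cutoff sweep and significance area

At every integer percentile c in [grid_lo, grid_hi] (default [10, 90]) the
score distribution is cut at its c-th linear-interpolation quantile; samples
with score ≥ cutoff form the "high" arm and a univariate Cox model of the
high indicator yields a Wald p-value. The curve is summarized by

    area = ∫ max(0, log10(α) − log10 p(c)) dc ,   α = 0.05,

a trapezoidal integral over the percentile axis. p = α contributes zero
(the boundary is exclusive); missing grid points contribute zero height.

* **Arm-size guard.** Cutoffs leaving either arm with < 10 samples or < 5
  events produce a missing p — small-arm Cox fits are numerically unstable
  and their p-values meaningless. Guarded points are reported as missing,
  never interpolated. The default grid bounds [10, 90] exist for the same
  reason; both are configurable.
* **Wald p, not likelihood ratio**, at each cutoff — the convention of the
  survival software stack this mirrors.
* The area depends only on the sample ranking, so it is invariant under
  monotone transforms of the score; this is asserted in the tests.
* No multiplicity correction is applied across cutoffs: the statistic
  deliberately aggregates the uncorrected curve; it is a robustness summary
  for *ranking* signatures, not an inferential p-value.

## Survival analysis

* **Kaplan–Meier** curves via lifelines; the numbers-at-risk table counts
  subjects with observed time ≥ t (at risk *immediately before* each
  requested time), which reproduces the hand example (times 1, 2, 3; events
  1, 1, 0; at-risk 3, 3, 2, 1 at t = 0, 1, 2, 3).
* **Log-rank** via lifelines' k-sample statistic (df = k − 1).
* **Cox fits** maximize the Breslow partial likelihood with an in-package
  Newton–Raphson solver (step-halving; suffix cumulative sums over the
  ascending-time risk sets; tied event times share one risk set). Breslow
  was chosen because it is the convention of the reference stack; the
  solver is validated against R `survival::coxph(ties="breslow")` (frozen
  values on a heavily tied dataset, agreement to 1e-8) and against lifelines
  on tie-free data. The solver is in-package rather than delegated because
  the percentile sweep and the interaction screen refit thousands of small
  models; a vectorized single-purpose Newton loop keeps the full acceptance
  suite inside minutes.
* **Failure modes are explicit.** Rank-deficient designs raise
  `RankDeficiencyError`; monotone likelihoods (separation — all high-risk
  subjects failing first, or |log HR| > 15 at "convergence") raise
  `ConvergenceError`. Silent zeros are never returned.
* **Interaction screen.** Per taxon passing the prevalence filter (default
  ≥ 10% of samples with a nonzero count — interaction terms are unstable
  below that), the model `hazard ~ hypoxia + microbe + hypoxia:microbe` is
  fitted and the interaction Wald p collected; BH adjustment is applied
  across tested taxa. Default microbe encoding is presence/absence (matching
  how such hits are validated downstream); log10 relative abundance with a
  1e-6 pseudocount is the alternative for dense taxa, whose presence
  indicator degenerates toward the constant 1 and is dropped as rank
  deficient. Taxa whose three-term fit fails are excluded from the table
  (and from the BH denominator).
* Models are unadjusted for demographics by default; any clinical column can
  be added as a covariate. This mirrors the common situation where strata
  show no demographic imbalance to control for.

## Differential abundance

* **Normalization**: median-of-ratios size factors against a pseudo-reference
  of per-taxon geometric means computed over *positive* counts (zeros
  ignored), rescaled to geometric mean 1. Ignoring zeros keeps the reference
  defined on zero-heavy microbe matrices. A sample with zero total counts is
  a named error.
* **Test**: per taxon, normalized group means m_low, m_high;
  log2FC = log2((m_high + c)/(m_low + c)) with pseudocount c = 0.5;
  dispersion φ by method of moments pooled across the two groups
  (floor 1e-8); delta-method SE from the NB variance law var = m + φm²;
  two-sided normal Wald p; BH across tested taxa. Taxa all-zero in both
  groups are excluded and counted in the log.
* This is intentionally a *self-contained* NB Wald test: no dispersion
  shrinkage, no outlier replacement, no independent filtering. It is
  validated by simulation calibration (type-I error 0.03–0.07 on 1,000 null
  taxa; log2FC recovery within 0.3 of a true value of 2.0), not by matching
  any reference tool's output. The size-factor step, which is standard, is
  cross-checked against an independent implementation in the tests.
* **Compositional caveat.** Median-of-ratios normalization assumes most taxa
  are unchanged. When a minority of taxa shift strongly in one direction,
  size factors absorb part of that shift and unchanged taxa acquire a small
  opposite-signed apparent fold change, which at large n can reach
  significance. This is inherent to the normalization family, visible in the
  README worked example (planted taxa recovered at log2FC ≈ +2.9, plus weak
  negative false calls), and is one reason the cross-cohort concordance rule
  (significant in both cohorts *and* same direction, default α = 0.05)
  exists: direction-consistent strong effects survive it, normalization
  artifacts rarely align.
* **Ecology utilities.** Bray–Curtis is computed from the textbook formula;
  a pair of all-zero samples has an undefined dissimilarity and is reported
  as NaN rather than 0 or 1. Presence/overlap uses detection threshold 0
  (any nonzero evidence) by default.

## Cohort comparison tables

Pearson chi-square (statistic Σ(O−E)²/E, df = (r−1)(c−1)) for categorical
variables; Yates continuity correction only when requested *and* the table
is 2×2. Continuous variables use equal-variance one-way ANOVA, reconstructed
from per-group (mean, SD, n) — algebraically identical to raw-data ANOVA
when the summaries come from the data, which is asserted against
`scipy.stats.f_oneway`. These defaults were chosen because they reproduce
the published cohort-table p-values from their printed summaries to the
printed precision (see `scripts/acceptance.py`): the r×c entries without
correction, the 2×2 entries with Yates — matching R's `chisq.test` default.
Two printed BMI rows are *not* reproducible from their printed summaries
under any equal-variance reconstruction (plausibly missing data or a
nonparametric test upstream) and are excluded from the reproduction set; the
public cohort's sex row requires the denominators implied by its printed
percentages (476/165) rather than the column totals.

## Synthetic cohort generator

One latent standard-normal hypoxia factor h_i per sample drives everything:

* **Expression**: log expr = a_g + β·h_i + ε, ε ~ N(0,1), exponentiated;
  baselines a_g ~ N(3, 1) give a TPM-like scale (median ≈ 20). Non-signature
  genes load zero.
* **Microbes**: count ~ NB(mean m_t · 2^(δ_t h_i)), var = m + φm²; base
  means m_t ~ logNormal(3, 1); δ_t = `taxon_log2fc` for the affected subset,
  else 0; φ = 0.5 by default, shared across taxa.
* **Survival**: T = −log U / (λ0 e^η), η = γ_h·1[h > median] +
  γ_x·1[h > median]·1[designated taxon present]; administrative censoring at
  a fixed horizon (matching overall-survival follow-up; no dropout model).
  The hazard uses the *true* latent median split, not the estimated score,
  so parameter-recovery tests isolate estimation error from scoring error.
* **Demographics** are sampled independently of h (sex/stage/race
  proportions approximating a US colorectal-cancer registry cohort; the
  treatment flag is Bernoulli(0.25)); an optional exponential-tilt knob can
  confound one categorical variable with h for sensitivity analyses.
* Defaults (n = 200 samples, 52 signature genes with β = 1, 5 of 50 taxa
  with δ = 1.5, λ0 = 0.1 per time unit with a 10-unit horizon → ≈ 60–70%
  events, γ_h = 0.7) were chosen once for adequate test power at desk scale;
  the source cohorts publish no effect sizes to copy.
* All randomness flows through one seeded `numpy` Generator; identical
  configurations are bit-identical. Paired cohorts share structural truth
  (affected taxa, signs, baselines) with independent noise and an optional
  log-normal baseline perturbation of SD `cohort_shift`.

What the generator does *not* emulate: read-level noise and classification
error, contamination, batch/center effects, compositional sequencing-depth
artifacts beyond what NB sampling induces, immune-cell fractions, and
informative censoring. Passing tests therefore demonstrate statistical
correctness of the pipeline under its own assumed model — not robustness to
those real-data pathologies.

## Problem sizes in the validation suite

The calibration and power checks run at the sizes stated in their tests:
1,000 null taxa and 1,000 null cohort replicates for type-I error, 200
replicates for the interaction-screen FDR, 100 replicates (n = 500) for
signature discrimination, 20–50 replicates for parameter recovery. These
sizes give Monte-Carlo standard errors comfortably inside the asserted
bands while keeping the whole suite at desk scale.

## Known limitations

* The NB Wald test is anti-conservative for very small groups (< ~30 per
  arm) where the moment dispersion estimate is noisy; calibration is
  established at n = 100 per arm.
* The interaction screen's presence encoding is uninformative for taxa
  detected in nearly all samples; use `log_abundance` for dense panels.
* The significance area is a ranking statistic; it has no null distribution
  attached and should not be read as evidence on its own.
* Sample-id matching is exact string equality by design; upstream id
  normalization must happen before loading.
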