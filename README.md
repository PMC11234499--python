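# oxystrat

Hypoxia metagene scoring, cutpoint-sweep survival robustness, and
hypoxia-stratified tumor-microbiome analysis for bulk RNA-seq cohorts.

## What problem this solves

Solid tumors — colorectal cancers in particular — are often hypoxic, and
hypoxia blunts the efficacy of radiotherapy. Bulk tumor RNA-seq lets you
approximate oxygenation with a *hypoxia metagene score* and, because a
fraction of the reads are of microbial origin, simultaneously profile the
intratumoral microbiome. `oxystrat` is a toolkit for the analysis that
connects the two: score tumors for hypoxia, stratify the cohort, ask which
microbes track the hypoxic state, and screen for microbes whose interaction
with hypoxia predicts overall survival. It is aimed at computational
oncology / microbiome researchers working with expression matrices, clinical
follow-up tables, and taxon count matrices.

## The statistics at its core

* **Hypoxia metagene score.** For a signature of G hypoxia-induced genes,
  sample *i* scores `sum_g sign(x_gi > median_g)` with −1 for ties: an
  integer in [−G, +G]. Only within-gene ranks matter, so the score is
  invariant to per-gene monotone transforms (TPM vs log-TPM). Strata are cut
  at score tertiles (low / medium / high) or the median.
* **Significance area.** Instead of trusting one cutpoint, the score is
  thresholded at every integer percentile c ∈ [10, 90]; each cutoff yields a
  univariate Cox Wald p-value for high-vs-low survival. The curve is
  summarized by `area = ∫ max(0, log10 α − log10 p(c)) dc` (α = 0.05) — the
  larger the area, the more robust the survival separation is to where you
  cut. Competing signatures are ranked by this area.
* **Survival models.** Kaplan–Meier product-limit curves with numbers-at-risk
  tables, k-sample log-rank tests, and Cox proportional-hazards fits
  maximizing the Breslow partial likelihood (Newton–Raphson, Wald
  inference). The interaction screen fits, per taxon,
  `hazard ~ hypoxia + microbe + hypoxia:microbe` and BH-adjusts the
  interaction p-values across taxa.
* **Differential abundance.** A self-contained negative-binomial Wald test on
  median-of-ratios normalized counts (variance law `m + φm²`, pooled
  method-of-moments dispersion), with Benjamini–Hochberg adjustment and a
  cross-cohort concordance rule (significant in both cohorts, same fold-change
  direction). Bray–Curtis dissimilarities and presence/absence overlap round
  out the ecology utilities.
* **Cohort tables.** Pearson chi-square (optional Yates for 2×2) and one-way
  ANOVA reconstructed exactly from per-group mean/SD/n — so published
  table-one p-values can be re-checked from the printed summaries alone.
* **Synthetic cohorts.** A seeded generator produces expression, microbe
  counts, demographics and survival that share one latent hypoxia factor, so
  every claim above is testable end to end without any access-controlled
  data.

## Worked example

```python
import oxystrat as ox

cfg = ox.SimulationConfig(n_samples=400, n_genes=200, n_signature_genes=52,
                          n_taxa=40, n_hypoxia_taxa=5,
                          hypoxia_log_hr=0.8, taxon_log2fc=1.5, seed=424242)
cohort = ox.simulate_cohort(cfg)

sig = ox.GeneSignature("planted", tuple(cohort.truth["signature_genes"]))
scores = ox.score_signature(cohort.expression, sig)
print(ox.score_summary(scores))
# {'mean': 0.0, 'sd': 30.68, 'median': -2.0}

strata = ox.stratify(scores, mode="tertile")
surv = ox.SurvivalData.from_clinical(cohort.clinical)
curve = ox.pvalue_curve(scores, surv)
print(round(curve.area, 1))
# 385.6

hilo = strata.strata[strata.strata.isin(["low", "high"])]
print(ox.logrank_test(ox.SurvivalData(table=surv.table.loc[hilo.index]), hilo))
# {'chi_square': 37.57, 'df': 1, 'p': 8.8e-10}

table = ox.nb_wald(cohort.microbes, hilo)
print(table.index[:5].tolist())
# ['Taxon_0031', 'Taxon_0006', 'Taxon_0024', 'Taxon_0015', 'Taxon_0028']
print(sorted(cohort.truth["affected_taxa"]) == sorted(table.index[:5]))
# True
```

The score summary shows the planted signature spreading the cohort over most
of the ±52 range; the sweep area of 385.6 means the Cox p-value stays far
below 0.05 across essentially the whole percentile grid (robust separation,
not a lucky cutpoint); the log-rank test confirms the high-vs-low tertile
survival split; and the NB Wald test ranks exactly the five planted
hypoxia-responsive taxa first, each with log2FC ≈ +2.9. (A handful of null
taxa also reach significance here with small *negative* fold changes — the
compositional side effect of median-of-ratios normalization when a few taxa
shift strongly in one direction; see `docs/methods.md`.)

The same analysis runs from the shell:

```bash
oxystrat simulate --out cohort/ --seed 1
oxystrat score --expr cohort/expression.tsv --signature BUFFA_HYPOXIA --out scores.tsv
oxystrat run --config run.yaml --out results/
```

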