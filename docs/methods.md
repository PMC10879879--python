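# Methods

This note documents the statistical model behind `metaboclock`, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the choices made where the design was genuinely open.

## The model

**Age screen.** For each metabolic feature, the Pearson product-moment
correlation `r` with chronological age is computed on pairwise-complete
observations among healthy *training* subjects. The two-sided p-value uses
the exact t transform `t = r·sqrt((n−2)/(1−r²))` on `n−2` degrees of
freedom. p-values are adjusted by Benjamini–Hochberg step-up with enforced
monotonicity (Bonferroni available via config). A feature is selected when
`|r| ≥ min_abs_r` (default 0.1) **and** `q ≤ max_q` (default 0.05).
Features constant on the training set, or with under 50% completeness, are
excluded with a logged reason code rather than an exception; exclusion
never happens silently. With the default generator (157 true age-trending
features among 1,603) the screen typically selects ~145–157 features —
the count is data-dependent, not a contract.

**Pathway scores.** Selected features are standardized using per-feature
mean and sd estimated on the healthy training subjects only, and those
parameters are applied unchanged to test, APL and CRC samples — held-out
samples are *not* re-centered, so disease shifts survive standardization
and no information leaks from evaluation data into the reference. Each
pathway's per-sample score is the weighted sum of its member z-values
divided by the number of mapped, retained members. The weights are the
features' age correlations `r_i`: the only age-linked per-feature quantity
available before aggregation; the sign carries trend direction, the
magnitude carries strength. Uniform weights are a config option. A feature
belonging to several pathways contributes fully to each (KEGG
multi-membership convention); pathways left without any selected feature
are dropped with a warning.

**Elastic-net clocks.** Both clocks (pathway-level and metabolite-level)
minimize

    (1/2n)‖y − β₀ − Xβ‖² + λ·(α‖β‖₁ + (1−α)/2·‖β‖₂²)

on internally standardized predictors (mean 0, sd 1 on the fit set).
Defaults: mixing α = 0.5; λ chosen by 10-fold cross-validated mean squared
error over a data-driven 100-point log grid. Both are configurable and
recorded in run manifests. The optimizer is scikit-learn's coordinate
descent, whose objective matches the one above exactly; the test suite
checks it against the closed-form single-predictor soft-threshold solution
and the KKT subgradient conditions (residual ≤ 1e-6), plus the OLS (λ→0)
and full-shrinkage (λ→∞) limits. Coefficients are reported on the
standardized scale along with raw-scale back-transforms. Importance scores
are `IS_j = 100·|β_j|/max_k|β_k|`; zero-coefficient predictors score 0 and
a predictor "contributes" to the model iff its coefficient is nonzero.
The metabolite clock is fit on a configured identified-biomarker panel
(with synthetic data, the nine named clock metabolites), then keeps
nonzero-coefficient predictors. Sex-stratified fits are the same code path
on a sex-restricted cohort.

**Train/test split.** Healthy subjects only, 75/25, stratified by sex ×
age decade with `round(0.75·n)` training subjects per stratum (singleton
strata go to training, logged). Deterministic given the seed.

**Evaluation.** Pearson r with a Fisher-z CI, `tanh(atanh(r) ±
1.96/sqrt(n−3))`, and the least-squares slope of predicted-on-actual age
with its standard-error CI. Correlations across populations are compared
by the Fisher-z heterogeneity chi-square (weights `n−3`), which for two
groups reduces to the standard two-sample z test.

**Δ age and subgroups.** `Δ = predicted − chronological` age. Thresholds
are global empirical quantiles (linear interpolation) of Δ in the healthy
**test split** — training residuals are optimistically small, so using
them would narrow the band; the held-out split gives nominal calibration
on fresh healthy subjects. Quantile pairs 2.5/97.5 (default), 5/95 and
10/90 are supported; assignment uses strict inequalities and boundary
values are "normal". Fitting thresholds on any non-healthy reference is
rejected by contract. Age-conditional (binned) thresholds are deliberately
not the default: subgroup membership is defined from the marginal Δ
distribution, with the quantile band rendered as horizontal offsets around
the identity line.

**Screening.** The metabolic panel calls every hypo subject positive. The
multi-target panel removes positives whose CEA is at or below 5 μg/L
(non-smokers) / 10 μg/L (smokers); these cutoffs are conventional clinical
reference limits, configurable and echoed in every result. A positive with
missing CEA stays positive with a warning (the filter cannot act);
"demote" is a config option. PPV is estimated on a simulated screening
population: `coverage × denominator` draws with replacement (default 30 ×
10,023), of which `coverage × numerator` come from the case pool (APL:
760; CRC all stages: 65) and the rest from the healthy *test-split* pool.
Drawing with replacement from a binary pool is a binomial draw at the
pool's positive rate, which is how it is implemented — distributionally
identical and O(1). One seeded population per configuration is the
default (a replicate mode averages several for variance diagnostics). The
CI uses the logit transform with `SE = sqrt(1/TP + 1/FP)`; if TP or FP is
zero the point estimate is returned flagged degenerate. "30× coverage"
is interpreted as 30× the incidence denominator; a pooled-count
interpretation is available via config. Stool-DNA and Septin9 comparator
PPVs are carried as reporting constants only, never computed.

**Mutation enrichment.** Among profiled stage I CRC subjects, the fraction
of mutants (KRAS/NRAS/BRAF) per subgroup, with 95% CIs from resampling the
mutant classification vector with replacement at the same size 10,000
times (2.5/97.5 interpolated quantiles). Subgroup thresholds are the main
analysis' thresholds, not recomputed per mutation subset.

**Permutation null.** To show the diseased cohorts' hypo excess is
specific to the age signature rather than a systematic pipeline bias, the
healthy subjects' age labels are permuted and the screening → clock →
Δ-age pipeline is refit per null model; the diseased hypo fraction across
models forms the null distribution, and `p = (1 + #{null ≥ observed}) /
(n_models + 1)`. Under permutation essentially no feature survives the BH
screen, so null models select the same *panel size* as the observed run by
rank of |r| — the pipeline keeps its shape and model capacity, only the
age link is broken. (A strict-threshold mode exists via config; with it,
null models that select nothing are skipped and counted, and the run fails
if more than 10% skip.) Default 100 models; the acceptance script uses 99
so the attainable p floor is 0.01.

## The synthetic cohort

The generator emulates the *statistical* structure the analysis assumes,
with cohort sizes (3,002 healthy / 715 APL / 1,088 + 427 + 417 CRC I–III),
decade age-bin probabilities and sex proportions matching the study
demographics.

* **Aging features:** `x = baseline + a·effective_age + N(0, σ)` with the
  slope solved analytically from the target correlation,
  `a = sign(r)·|r|/sqrt(1−r²)·σ/sd(age)`, so empirical correlations land
  on target up to Fisher-z sampling error. 157 of 1,603 features carry
  trends; the rest are pure noise. Background aging features draw
  `|r| ∈ [0.10, 0.28]`; the nine clock metabolites have fixed targets from
  0.50 (prolylleucine) to 0.75 (kynurenine), signs per the serum-aging
  literature (DHEA-sulfate declines; the rest rise). The targets were set
  so the nine-marker panel's combined correlation,
  `R² = Σλ_i/(1+Σλ_i)` with `λ_i = r_i²/(1−r_i²)`, is ≈ 0.87 (r ≈ 0.93),
  the regime reported for serum metabolomic clocks, and so the panel
  separates cleanly from the background — which is what makes
  importance-score recovery a meaningful test.
* **Disease:** a single age-coherent mechanism — `effective_age = age −
  shift` with `shift ~ max(0, N(8 y, 4 y))` for every diseased cohort — is
  the minimal structure reproducing a systematic downward deviation of
  predicted age. No feature-specific disease effects. The 8-year mean is a
  simulation choice (no published effect size exists); mutation carriers
  get +4 years on top, so mutant enrichment in the hypo subgroup has a
  known direction.
* **Mutations:** a 412-subject profiled subset of stage I CRC receives
  independent Bernoulli flags at prevalences 0.398 / 0.034 / 0.044
  (KRAS/NRAS/BRAF); everyone else's flags are missing.
* **CEA:** log-normal baseline (median 1.5 μg/L) with a cohort-dependent
  probability of drawing from an elevated component (median 12 μg/L):
  8% healthy, 15% APL, 35–60% CRC by stage. Elevation is independent of
  the metabolome given cohort — the multi-target filter's value comes
  purely from case-enrichment of elevation.
* **Scale:** intensities live on a log-like additive scale with
  homoscedastic noise; downstream standardization makes the absolute scale
  immaterial, so no heteroscedastic MS noise model is attempted.
* **Not emulated:** batch effects, injection-order drift, limit-of-
  detection censoring, feature-feature correlation beyond the shared age
  factor, and any missingness mechanism beyond completely-at-random
  (optional rate). Passing tests therefore demonstrate correctness of the
  statistics under the stated model, not robustness to real-world MS
  artifacts.

Everything is reproducible: a spec plus seed yields bit-identical outputs,
and all stage seeds derive from one master seed by stage-name hashing.

## Numerical choices and edge cases

* Missing values are an explicit NA, never a numeric sentinel; "" / "NA" /
  "NaN" are recognized on read; round-trips preserve 12 significant
  digits.
* Correlations are clipped to [−1, 1] against floating-point overshoot;
  `|r| = 1` maps to p = 0.
* Degenerate inputs (constant features, constant predictions, zero
  mutants, empty cohorts) produce flagged results or logged exclusions,
  not crashes; genuinely contradictory requests (zero noise with |r| < 1,
  non-healthy threshold reference, empty λ grid) raise.
* Quantiles use linear interpolation between order statistics everywhere
  (thresholds, bootstrap CIs); the threshold estimator requires at least
  `ceil(1/min(q_lo, 1−q_hi))` reference subjects.
* Elastic-net convergence tolerance defaults to scikit-learn's 1e-4;
  oracle tests tighten it to machine precision.

## Problem sizes used in tests

Unit tests run on cohorts of a few hundred subjects and 120–300 features;
the calibration check uses 9,000 healthy subjects (3,000 to fit, 6,000
held out) with 150 features; clock recovery uses 20 replicates of 2,000
healthy subjects at the full 1,603 features; the end-to-end checks and the
acceptance script use the full default cohort (5,649 × 1,603) with a
59–99-model permutation null. These sizes give each check comfortable
statistical margins while keeping the whole suite under a minute of
compute.

## Known limitations

* The pathway "weighted sum" weights and the identified-panel composition
  are design choices documented above; with real data both should be
  revisited against the available annotation evidence.
* The permutation null's rank-based panel selection measures
  signature-specificity at fixed model capacity; it does not test the
  selection step's false-discovery behavior (the screen's BH calibration
  is tested separately).
* PPV estimates inherit the sparsity of the healthy test pool: with ~750
  controls and rare positives, the multi-target FP count is small and its
  PPV CI wide — visible in the acceptance output, and faithful to how
  such panels behave at screening incidence.
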