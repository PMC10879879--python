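# metaboclock

Metabolomic aging clocks and hypo-aging screening for colorectal cancer.

Serum metabolomes drift with age in a reproducible way. A *metabolic aging
clock* exploits this: regress chronological age on blood metabolite
measurements in a healthy reference population, then read each subject's
**Δ metabolic age** — predicted minus chronological age — as a summary of
whether their metabolome looks older (Δ > 0, "hyper") or younger (Δ < 0,
"hypo") than their birthdate says. Patients with colorectal advanced
precancerous lesions (APL) or colorectal cancer (CRC) show a systematic
*hypo*-aging shift, which makes hypo membership usable as a blood-based
screening call. This package implements that whole analysis as a tested,
reusable pipeline for anyone working with processed serum metabolomics
feature matrices: epidemiologists building aging clocks, and
methods-minded readers who want every statistical step reproducible on
synthetic data with known ground truth.

## What it computes

1. **Age screen** — per-feature Pearson correlation with age on a healthy
   training split; two-sided p from `t = r sqrt((n-2)/(1-r²))`;
   Benjamini–Hochberg control; selection at `|r| ≥ r_min`, `q ≤ q_max`.
2. **Pathway scores** — per subject and KEGG-style pathway P,
   `score_P = Σ_{i∈P} w_i z_i / |P|` where `z_i` are feature values
   standardized on the healthy training reference and `w_i = r_i` (each
   feature's age correlation).
3. **Elastic-net clocks** — on pathway scores or on an identified
   metabolite panel, minimize
   `(1/2n)‖y − β₀ − Xβ‖² + λ(α‖β‖₁ + (1−α)/2 ‖β‖₂²)`
   with mixing α = 0.5 and λ by 10-fold cross-validated MSE over a
   100-point log grid; importance score
   `IS_j = 100·|β_j|/max_k|β_k|` on standardized coefficients.
4. **Δ-age subgroups** — thresholds are the 2.5%/97.5% (also 5/95, 10/90)
   empirical quantiles of Δ in the held-out healthy test split; hypo/hyper
   assignment is strict, boundaries are "normal".
5. **Screening PPVs** — hypo membership (optionally AND serum CEA above
   5 μg/L non-smokers / 10 μg/L smokers) called positive; a screening
   population is bootstrapped at 30× coverage to incidence 760/10,023
   (APL) or 65/10,023 (CRC); `PPV = TP/(TP+FP)` with a logit-transform CI,
   `SE = sqrt(1/TP + 1/FP)`.
6. **Inference** — KRAS/NRAS/BRAF enrichment in the hypo subgroup with
   10,000-resample bootstrap CIs, and a permutation null that refits the
   whole pipeline on age-shuffled healthy labels to check the diseased
   cohorts' excess hypo fraction is signature-specific.

A synthetic-cohort generator (`metaboclock.simulate`) reproduces the
statistical structure all of this assumes — age-trending features with
prescribed correlations, nine named clock metabolites with
literature-consistent signs (kynurenine ↑, phenylalanine ↑, DHEA-sulfate ↓,
…), disease as an effective-age shift, CEA elevation enriched in CRC, and
stage I mutation flags — with full ground truth for parameter-recovery
tests.

## Worked example

```python
from metaboclock import (SimulationSpec, simulate_cohort,
                         PipelineConfig, run_pipeline)

cohort, features, pathways, truth = simulate_cohort(SimulationSpec(seed=7))
res = run_pipeline(cohort, features, pathways, PipelineConfig(seed=7))

ev = res.metabolite_eval["test"]
print(f"clock test r = {ev.r:.3f} (95% CI {ev.r_ci[0]:.3f}-{ev.r_ci[1]:.3f})")
print(res.cohort_fractions[res.cohort_fractions.subgroup == "hypo"])
```

prints (abridged):

```
nine-metabolite clock, held-out healthy subjects (n=750):
  r = 0.929 (95% CI 0.918-0.938), slope = 0.847
delta-age thresholds (2.5%/97.5% of healthy test split): -8.02 y, +7.93 y
  hypo fraction healthy :   2.5% (2.0-3.1)
  hypo fraction APL     :  42.9% (39.3-46.6)
  hypo fraction CRC_I   :  48.2% (45.2-51.2)
  PPV APL:clock                   :  57.7% (57.0-58.5)
  PPV CRC_all_stages:clock        :  10.4% (9.8-11.1)
  PPV CRC_all_stages:multitarget  :  21.5% (19.5-23.6)
mutation  n_mutant  hypo  ...  hypo_ci_lo  hypo_ci_hi
    kras       158 0.696  ...       0.620       0.766
```

Reading: the nine-metabolite clock predicts held-out healthy age with
r ≈ 0.93; by construction ~2.5% of healthy subjects fall below the lower
Δ-age quantile, but ~43–48% of APL/stage I CRC subjects do (their
metabolomes were simulated "younger" than their age); at population
incidence that hypo call alone yields a 10–58% PPV depending on target,
and adding the CEA filter raises the CRC PPV from ~10% to ~22%; KRAS
mutants are further enriched in the hypo subgroup (69.6% vs 48.2% of all
stage I).

The same stages are available from a shell:

```sh
metaboclock simulate --seed 7 --out-dir data/
metaboclock screen --cohort data/cohort.tsv --features data/features.tsv \
    --seed 7 --out data/screen.tsv
metaboclock run-all --cohort data/cohort.tsv --features data/features.tsv \
    --pathways data/pathways.gmt --seed 7 --out-dir results/
```

Each subcommand writes TSV outputs plus a JSON manifest recording inputs,
seed and version.

## Layout

| module | contents |
| --- | --- |
| `metaboclock.io` | validated cohort/feature/GMT readers and writers, `PipelineConfig`, per-stage seed derivation |
| `metaboclock.simulate` | `SimulationSpec`, `simulate_cohort`, ground truth |
| `metaboclock.screen` | `AgeCorrelationScreen`, `pearson_age_correlation`, `bh_adjust` |
| `metaboclock.pathways` | `PathwayScorer`, standardization, pathway score |
| `metaboclock.clock` | `MetabolicAgeClock` (elastic net), split, evaluation, importance |
| `metaboclock.delta` | Δ age, quantile thresholds, `DeltaAgeClassifier`, subgroup fractions |
| `metaboclock.screening` | hypo classifier, CEA filter, population bootstrap, logit-CI PPV |
| `metaboclock.inference` | mutation enrichment bootstraps, permutation null |
| `metaboclock.pipeline` | `run_pipeline` orchestration |
| `metaboclock.cli` | `metaboclock` command-line tool |

See `docs/methods.md` for the statistical details and design choices.
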