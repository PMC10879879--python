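"""Mutation-enrichment bootstraps and the permutation-null check.

Enrichment: among stage I CRC subjects profiled for a mutation, the
fraction of mutants falling in each delta-age subgroup, with 95% CIs from
resampling the mutant classification vector with replacement 10,000 times.

Permutation null: to check that the diseased cohorts' excess hypo-aging
membership is specific to the age-related signature (not a systematic bias
of the pipeline), the age labels of healthy subjects are permuted and the
whole screening -> clock -> delta-age pipeline is refit; the diseased hypo
fraction under each of ``n_models`` permuted clocks forms the null
distribution for the observed fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clock import MetabolicAgeClock, split_train_test
from .delta import DeltaAgeClassifier, compute_delta
from .io import CRC_COHORTS, PipelineConfig, stage_seed
from .screen import AgeCorrelationScreen

logger = logging.getLogger("metaboclock")


# ---------------------------------------------------------------------------
# mutation enrichment


def mutation_subgroup_fractions(subgroups: pd.Series, cohort: pd.DataFrame,
                                mutation: str) -> dict | None:
    """Fraction of mutants in each subgroup among profiled stage I CRC.

    Returns ``{"n_mutant": k, "hypo": f, "normal": f, "hyper": f}`` (the
    three fractions sum to 1), or None with a warning when no mutants.
    """
    if mutation not in cohort.columns:
        raise ValueError(f"cohort table has no column {mutation!r}")
    flags = cohort[mutation]
    mutants = cohort.index[(cohort["cohort"] == "CRC_I")
                           & (flags == True)]  # noqa: E712 (boolean dtype w/ NA)
    if len(mutants) == 0:
        logger.warning("stage=enrichment mutation=%s zero mutants, omitted",
                       mutation)
        return None
    sub = pd.Series(subgroups).reindex(mutants)
    out = {"n_mutant": int(len(mutants))}
    for g in ("hypo", "normal", "hyper"):
        out[g] = float((sub == g).mean())
    return out


def bootstrap_fraction_ci(membership, B: int = 10_000, seed: int = 0
                          ) -> tuple[float, float]:
    """Percentile bootstrap CI for a binary-vector fraction.

    B resamples of the full vector with replacement (equivalently binomial
    counts at the observed fraction); 2.5/97.5 interpolated quantiles.
    """
    x = np.asarray(membership, dtype=bool)
    if x.size < 1:
        raise ValueError("membership vector must be nonempty")
    if B < 100:
        logger.warning("stage=bootstrap B=%d < 100: quantiles are unstable", B)
    rng = np.random.default_rng(seed)
    fracs = rng.binomial(x.size, x.mean(), size=B) / x.size
    lo, hi = np.quantile(fracs, [0.025, 0.975], method="linear")
    return float(lo), float(hi)


def mutation_enrichment(subgroups: pd.Series, cohort: pd.DataFrame,
                        mutations=("kras", "nras", "braf"),
                        B: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Enrichment table: per mutation, hypo fraction with bootstrap CI."""
    rows = []
    for i, m in enumerate(mutations):
        frac = mutation_subgroup_fractions(subgroups, cohort, m)
        if frac is None:
            continue
        mutants = cohort.index[(cohort["cohort"] == "CRC_I")
                               & (cohort[m] == True)]  # noqa: E712
        in_hypo = (pd.Series(subgroups).reindex(mutants) == "hypo").to_numpy()
        lo, hi = bootstrap_fraction_ci(in_hypo, B=B, seed=seed + i)
        rows.append({"mutation": m, "n_mutant": frac["n_mutant"],
                     "hypo": frac["hypo"], "normal": frac["normal"],
                     "hyper": frac["hyper"], "hypo_ci_lo": lo,
                     "hypo_ci_hi": hi})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation null


@dataclass
class NullModelResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_models: int
    n_skipped: int


def _hypo_fraction_once(features: pd.DataFrame, cohort: pd.DataFrame,
                        config: PipelineConfig, split: pd.Series,
                        panel_size: int, rng: np.random.Generator,
                        permute: bool, target_cohorts) -> float:
    """One screening -> clock -> delta-age pass; diseased hypo fraction."""
    healthy = cohort[cohort["cohort"] == "healthy"]
    ages = healthy["age"].copy()
    if permute:
        ages[:] = rng.permutation(ages.to_numpy())
    train_ids = split.index[split == "train"]
    test_ids = split.index[split == "test"]

    screen = AgeCorrelationScreen(
        min_abs_r=0.0 if config.null_selection == "rank" else config.min_abs_r,
        max_q=1.0 if config.null_selection == "rank" else config.max_q,
        multiple_testing=config.multiple_testing,
        min_completeness=config.min_completeness,
    ).fit(features.loc[train_ids], ages.loc[train_ids])
    res = screen.results_
    if config.null_selection == "rank":
        panel = res["r"].abs().nlargest(panel_size).index.tolist()
    else:
        panel = res.index[res["selected"]].tolist()
    if not panel:
        raise RuntimeError("empty panel under permutation")

    model = MetabolicAgeClock(
        l1_ratio=config.l1_ratio, n_lambdas=config.n_lambdas,
        cv=config.cv_folds,
        random_state=int(rng.integers(2**31)),
    ).fit(features.loc[train_ids, panel], ages.loc[train_ids])

    ref_ids = test_ids if config.threshold_reference == "test" else healthy.index
    delta_ref = compute_delta(model.predict(features.loc[ref_ids, panel]),
                              ages.loc[ref_ids])
    clf = DeltaAgeClassifier(config.q_lo, config.q_hi).fit(delta_ref)

    diseased = cohort.index[cohort["cohort"].isin(target_cohorts)]
    delta_dis = compute_delta(model.predict(features.loc[diseased, panel]),
                              cohort.loc[diseased, "age"])
    return float((clf.predict(delta_dis) == "hypo").mean())


def permutation_null(features: pd.DataFrame, cohort: pd.DataFrame,
                     config: PipelineConfig, n_models: int = 100,
                     seed: int | None = None, panel_size: int = 9,
                     target_cohorts=("APL",) + CRC_COHORTS
                     ) -> NullModelResult:
    """Refit the pipeline under healthy age-label permutations.

    The observed statistic is the diseased cohorts' hypo fraction from the
    unpermuted pipeline run through the identical code path; each null
    model permutes healthy ages, refits screening, clock and thresholds,
    and records the diseased hypo fraction.  Empirical p-value:
    (1 + #{null >= observed}) / (n_models + 1).  Models whose refit fails
    are skipped and counted; the run fails if more than 10% skip.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(stage_seed(seed, "null-check"))
    healthy = cohort[cohort["cohort"] == "healthy"]
    split = split_train_test(healthy, config.train_fraction,
                             stage_seed(seed, "split"))

    observed = _hypo_fraction_once(features, cohort, config, split,
                                   panel_size, rng, permute=False,
                                   target_cohorts=target_cohorts)
    null, skipped = [], 0
    for i in range(n_models):
        try:
            null.append(_hypo_fraction_once(
                features, cohort, config, split, panel_size, rng,
                permute=True, target_cohorts=target_cohorts))
        except (ValueError, RuntimeError) as exc:
            skipped += 1
            logger.warning("stage=null-check model=%d skipped: %s", i, exc)
    if skipped > 0.1 * n_models:
        raise RuntimeError(
            f"{skipped}/{n_models} null models failed; inputs unsuitable")
    null_arr = np.asarray(null)
    p = (1.0 + np.sum(null_arr >= observed)) / (len(null_arr) + 1.0)
    logger.info("stage=null-check observed=%.4f null_mean=%.4f p=%.4g "
                "n_models=%d skipped=%d", observed, null_arr.mean(), p,
                len(null_arr), skipped)
    return NullModelResult(observed, null_arr, float(p), len(null_arr), skipped)
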