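"""Turn hypo-aging membership into a cancer screening test.

The metabolic panel calls every subject in the hypo delta-age subgroup
positive; the multi-target panel additionally demotes positives whose
serum CEA is at or below the smoking-status-dependent cutoff.  Because
case/control proportions in a study cohort do not reflect population
prevalence, the positive predictive value is estimated on a simulated
screening population: draws with replacement at a coverage multiple of the
incidence denominator, cases at the target incidence from the case
prediction pool and the remainder from the healthy test-split pool.  The
PPV confidence interval uses the logit transform with a central-limit
standard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

logger = logging.getLogger("metaboclock")

#: External comparator PPVs carried as reporting constants only (stool-DNA
#: and Septin9 methylation screening tests); never computed here.
COMPARATOR_PPVS = {
    "cologuard": {"APL": (0.200, (0.180, 0.220)),
                  "CRC_all_stages": (0.0372, (0.0285, 0.0476))},
    "septin9": {"APL": (0.095, (0.091, 0.099)),
                "CRC_all_stages": (0.023, (0.018, 0.029))},
}


@dataclass
class ScreenConfig:
    """One screening scenario: target condition, incidence, CEA handling."""

    target: str = "CRC_all_stages"              # or "APL"
    incidence: tuple[int, int] = (65, 10023)    # numerator, denominator
    coverage: int = 30
    cea_cutoff_nonsmoker: float = 5.0
    cea_cutoff_smoker: float = 10.0
    use_cea_filter: bool = False
    missing_cea: str = "keep"                    # or "demote"
    seed: int = 0

    def __post_init__(self) -> None:
        num, den = self.incidence
        if not 0 < num < den:
            raise ValueError("incidence must satisfy 0 < numerator < denominator")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if self.target not in ("APL", "CRC_all_stages"):
            raise ValueError("target must be 'APL' or 'CRC_all_stages'")
        if self.missing_cea not in ("keep", "demote"):
            raise ValueError("missing_cea must be 'keep' or 'demote'")


@dataclass
class ScreenResult:
    tp: int
    fp: int
    ppv: float
    ci: tuple[float, float] | None
    degenerate: bool
    config: dict = field(default_factory=dict)


def classify_hypo(subgroups) -> np.ndarray:
    """Binary screening call: positive <=> hypo subgroup membership."""
    labels = np.asarray(subgroups, dtype=object)
    return labels == "hypo"


def apply_cea_filter(predictions, cohort: pd.DataFrame,
                     cutoff_nonsmoker: float, cutoff_smoker: float,
                     missing_cea: str = "keep") -> np.ndarray:
    """Demote positives with normal CEA for their smoking status.

    Never creates a positive.  Missing CEA on a positive is kept positive
    with a warning by default (the filter cannot act), or demoted when
    ``missing_cea == "demote"``.  Missing smoker status uses the stricter
    (non-smoker) cutoff.
    """
    pred = np.asarray(predictions, dtype=bool).copy()
    cea = pd.to_numeric(cohort.get("cea"), errors="coerce").to_numpy(dtype=float)
    if np.any(cea < 0):
        raise ValueError("negative CEA values in cohort table")
    smoker = (cohort["smoker"].fillna(False).to_numpy(dtype=bool)
              if "smoker" in cohort.columns else np.zeros(len(cohort), bool))
    cutoff = np.where(smoker, cutoff_smoker, cutoff_nonsmoker)

    missing = ~np.isfinite(cea)
    n_missing_pos = int((pred & missing).sum())
    if n_missing_pos:
        logger.warning("stage=cea_filter n_positives_missing_cea=%d policy=%s",
                       n_missing_pos, missing_cea)
    normal_cea = np.isfinite(cea) & (cea <= cutoff)
    pred &= ~normal_cea
    if missing_cea == "demote":
        pred &= ~missing
    return pred


def simulate_population(case_preds, control_preds, cfg: ScreenConfig,
                        seed: int | np.random.Generator | None = None
                        ) -> tuple[int, int]:
    """Bootstrap a screening population at the configured incidence.

    Draws ``coverage * denominator`` subjects with replacement:
    ``coverage * numerator`` from the case prediction pool and the rest
    from the control (healthy test-split) pool.  TP is the number of
    positive cases drawn, FP the number of positive controls drawn.
    Sampling with replacement from a binary pool is a binomial draw at the
    pool's positive rate, which is how it is implemented.
    """
    case = np.asarray(case_preds, dtype=bool)
    control = np.asarray(control_preds, dtype=bool)
    if case.size == 0 or control.size == 0:
        raise ValueError("both prediction pools must be nonempty")
    num, den = cfg.incidence
    n_case = cfg.coverage * num
    n_control = cfg.coverage * den - n_case
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(cfg.seed if seed is None else seed))
    tp = int(rng.binomial(n_case, case.mean()))
    fp = int(rng.binomial(n_control, control.mean()))
    logger.info("stage=simulate_population target=%s n_case=%d n_total=%d "
                "TP=%d FP=%d", cfg.target, n_case, cfg.coverage * den, tp, fp)
    return tp, fp


def ppv_with_logit_ci(tp: int, fp: int, level: float = 0.95,
                      config: dict | None = None) -> ScreenResult:
    """PPV = TP/(TP+FP) with a logit-transform CLT confidence interval.

    CI = inverse-logit(logit(PPV) +/- z * SE), SE = sqrt(1/TP + 1/FP).
    When TP or FP is zero the point estimate is returned with the CI
    flagged degenerate.
    """
    if tp < 0 or fp < 0:
        raise ValueError("counts must be nonnegative")
    if tp + fp == 0:
        raise ValueError("PPV undefined: no predicted positives")
    ppv = tp / (tp + fp)
    if tp == 0 or fp == 0:
        return ScreenResult(tp, fp, ppv, None, True, config or {})
    from scipy import stats
    z = stats.norm.ppf(0.5 + level / 2)
    se = np.sqrt(1.0 / tp + 1.0 / fp)
    lo, hi = expit(logit(ppv) - z * se), expit(logit(ppv) + z * se)
    return ScreenResult(tp, fp, ppv, (float(lo), float(hi)), False, config or {})


def analytic_ppv(sensitivity: float, fpr: float, prevalence: float) -> float:
    """Closed-form Bayes PPV: Se*p / (Se*p + FPR*(1-p))."""
    num = sensitivity * prevalence
    return num / (num + fpr * (1.0 - prevalence))


def run_screen(subgroups: pd.Series, cohort: pd.DataFrame, split: pd.Series,
               cfg: ScreenConfig, replicates: int = 1,
               seed: int | None = None) -> ScreenResult:
    """End-to-end screening evaluation for one configuration.

    Case pool: APL subjects (target "APL") or all CRC stages
    ("CRC_all_stages").  Control pool: healthy subjects in the test split.
    With ``replicates > 1`` the TP/FP counts are averaged over seeded
    simulated populations (variance diagnostic mode).
    """
    subgroups = pd.Series(subgroups)
    positive = pd.Series(classify_hypo(subgroups), index=subgroups.index)
    if cfg.use_cea_filter:
        positive = pd.Series(
            apply_cea_filter(positive.to_numpy(), cohort.loc[positive.index],
                             cfg.cea_cutoff_nonsmoker, cfg.cea_cutoff_smoker,
                             cfg.missing_cea),
            index=positive.index)

    coh = cohort["cohort"]
    case_ids = (coh[coh == "APL"].index if cfg.target == "APL"
                else coh[coh.isin(("CRC_I", "CRC_II", "CRC_III"))].index)
    control_ids = coh[(coh == "healthy")
                      & (split.reindex(coh.index) == "test")].index
    case = positive.reindex(case_ids).to_numpy(dtype=bool)
    control = positive.reindex(control_ids).to_numpy(dtype=bool)

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    tps, fps = zip(*(simulate_population(case, control, cfg, rng)
                     for _ in range(replicates)))
    tp, fp = int(round(np.mean(tps))), int(round(np.mean(fps)))
    echo = {"target": cfg.target, "incidence": list(cfg.incidence),
            "coverage": cfg.coverage, "use_cea_filter": cfg.use_cea_filter,
            "cea_cutoffs": [cfg.cea_cutoff_nonsmoker, cfg.cea_cutoff_smoker],
            "n_case_pool": int(case.size), "n_control_pool": int(control.size),
            "case_positive_rate": float(case.mean()),
            "control_positive_rate": float(control.mean()),
            "replicates": replicates}
    return ppv_with_logit_ci(tp, fp, config=echo)
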