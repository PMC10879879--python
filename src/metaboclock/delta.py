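"""Delta metabolic age and hypo/normal/hyper subgroup assignment.

Delta age is predicted minus chronological age: negative means the
metabolome looks younger than the subject.  Subgroup thresholds are
empirical quantiles (default 2.5%/97.5%) of delta age in a declared
*healthy* reference set -- by default the held-out healthy test split, so
training residual optimism never narrows the band.  A subject is "hypo"
strictly below the lower threshold, "hyper" strictly above the upper one,
otherwise "normal" (boundary values are normal).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger("metaboclock")

SUBGROUPS = ("hypo", "normal", "hyper")


def compute_delta(pred, actual) -> np.ndarray:
    """Delta_i = predicted_i - actual_i (positive = hyper direction)."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("length mismatch between predicted and actual ages")
    return pred - actual


def subgroup_thresholds(delta_healthy, q_lo: float, q_hi: float
                        ) -> tuple[float, float]:
    """Empirical (linear-interpolated) quantiles of healthy delta age."""
    if not 0 < q_lo < q_hi < 1:
        raise ValueError("need 0 < q_lo < q_hi < 1")
    delta = np.asarray(delta_healthy, dtype=float)
    n_min = math.ceil(1.0 / min(q_lo, 1.0 - q_hi))
    if delta.size < n_min:
        raise ValueError(
            f"need at least {n_min} healthy reference subjects for the "
            f"quantile pair ({q_lo}, {q_hi}); got {delta.size}")
    lo, hi = np.quantile(delta, [q_lo, q_hi], method="linear")
    return float(lo), float(hi)


def assign_subgroups(delta, thresholds: tuple[float, float]) -> np.ndarray:
    """Label each delta: hypo < lo <= normal <= hi < hyper (strict)."""
    lo, hi = thresholds
    if lo > hi:
        raise ValueError("thresholds must be ordered")
    delta = np.asarray(delta, dtype=float)
    labels = np.full(delta.shape, "normal", dtype=object)
    labels[delta < lo] = "hypo"
    labels[delta > hi] = "hyper"
    return labels


class DeltaAgeClassifier(BaseEstimator):
    """Quantile-band subgroup classifier fitted on healthy delta ages.

    ``fit`` accepts an optional cohort-label vector and refuses any
    non-healthy reference subject, so thresholds can only ever come from
    the healthy population.
    """

    def __init__(self, q_lo: float = 0.025, q_hi: float = 0.975):
        self.q_lo = q_lo
        self.q_hi = q_hi

    def fit(self, delta_healthy, cohort_labels=None):
        if cohort_labels is not None:
            labels = np.asarray(cohort_labels, dtype=object)
            bad = set(labels) - {"healthy"}
            if bad:
                raise ValueError(
                    f"threshold reference must be healthy-labeled; found {bad}")
        self.thresholds_ = subgroup_thresholds(delta_healthy, self.q_lo, self.q_hi)
        self.n_reference_ = int(np.asarray(delta_healthy).size)
        logger.info("stage=delta_age q=(%g,%g) thresholds=(%.3f,%.3f) n_ref=%d",
                    self.q_lo, self.q_hi, *self.thresholds_, self.n_reference_)
        return self

    def predict(self, delta) -> np.ndarray:
        check_is_fitted(self, "thresholds_")
        return assign_subgroups(delta, self.thresholds_)


def subgroup_fractions(labels: pd.Series, cohort: pd.Series,
                       B: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Per-cohort subgroup fractions with percentile bootstrap CIs.

    Subjects are resampled with replacement within each cohort B times
    (implemented as multinomial label counts, which is the same resampling
    distribution); the CI is the 2.5/97.5 percentile of resampled
    fractions.  Empty cohorts are omitted with a warning.
    """
    labels = pd.Series(labels)
    cohort = pd.Series(cohort).loc[labels.index]
    rng = np.random.default_rng(seed)
    rows = []
    for coh in pd.unique(cohort):
        sub = labels[cohort == coh]
        n = len(sub)
        if n == 0:
            logger.warning("stage=subgroup_fractions cohort=%s empty, omitted", coh)
            continue
        p_hat = np.array([(sub == g).mean() for g in SUBGROUPS])
        resampled = rng.multinomial(n, p_hat, size=B) / n
        los, his = np.percentile(resampled, [2.5, 97.5], axis=0)
        for g, p, lo, hi in zip(SUBGROUPS, p_hat, los, his):
            rows.append({"cohort": coh, "subgroup": g, "n": n,
                         "fraction": p, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)
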