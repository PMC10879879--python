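"""Screen metabolic features for association with chronological age.

Each feature is tested by Pearson correlation with age on pairwise-complete
observations; two-sided p-values come from the exact t transform and are
adjusted by Benjamini-Hochberg step-up (Bonferroni optional).  A feature is
*selected* when |r| >= ``min_abs_r`` and q <= ``max_q``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger("metaboclock")


def pearson_age_correlation(x, age) -> tuple[float, float, int]:
    """Pearson r of one feature with age on pairwise-complete observations.

    Returns ``(r, p, n_used)``; ``r`` and ``p`` are NaN when fewer than 3
    complete pairs remain or either vector is constant on them (the caller
    excludes such features with a reason code rather than aborting).

    The p-value uses t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of
    freedom, two-sided.
    """
    x = np.asarray(x, dtype=float)
    age = np.asarray(age, dtype=float)
    if x.shape != age.shape:
        raise ValueError("x and age must have the same length")
    ok = np.isfinite(x) & np.isfinite(age)
    n = int(ok.sum())
    if n < 3:
        return (np.nan, np.nan, n)
    xs, ys = x[ok], age[ok]
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return (np.nan, np.nan, n)
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return (r, 0.0, n)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return (r, float(p), n)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (order-preserving).

    q_(i) = min over j >= i of p_(j) * m / j, clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def bonferroni_adjust(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    return np.clip(p * p.size, 0.0, 1.0)


class AgeCorrelationScreen(BaseEstimator, TransformerMixin):
    """Univariate age-association screen as a feature selector.

    Parameters
    ----------
    min_abs_r : float
        Minimum absolute Pearson correlation with age.
    max_q : float
        Maximum adjusted p-value.
    multiple_testing : {"bh", "bonferroni"}
        Adjustment procedure.
    min_completeness : float
        Features with a lower fraction of non-missing values are excluded
        before testing (reason ``low_completeness``).

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per feature: r, p, q, n_used, selected, reason.
    support_ : ndarray of bool
    selected_features_ : list of str
    """

    def __init__(self, min_abs_r: float = 0.1, max_q: float = 0.05,
                 multiple_testing: str = "bh", min_completeness: float = 0.5):
        self.min_abs_r = min_abs_r
        self.max_q = max_q
        self.multiple_testing = multiple_testing
        self.min_completeness = min_completeness

    def fit(self, X, y):
        X = pd.DataFrame(X)
        age = np.asarray(y, dtype=float)
        if len(X) != age.size:
            raise ValueError("X and y must have the same number of samples")
        if self.multiple_testing not in ("bh", "bonferroni"):
            raise ValueError("multiple_testing must be 'bh' or 'bonferroni'")
        feats = [str(c) for c in X.columns]
        values = X.to_numpy(dtype=float)
        n, m = values.shape

        completeness = np.isfinite(values).mean(axis=0)
        r = np.full(m, np.nan)
        p = np.full(m, np.nan)
        n_used = np.zeros(m, dtype=int)
        reason = np.array([""] * m, dtype=object)

        testable = completeness >= self.min_completeness
        reason[~testable] = "low_completeness"

        clean = testable & ~np.isnan(values).any(axis=0)
        if np.isfinite(age).all() and clean.any():
            # vectorized complete-case path
            idx = np.where(clean)[0]
            V = values[:, idx]
            vc = V - V.mean(axis=0)
            ac = age - age.mean()
            sxx = (vc * vc).sum(axis=0)
            syy = ac @ ac
            with np.errstate(invalid="ignore", divide="ignore"):
                rv = (vc.T @ ac) / np.sqrt(sxx * syy)
            rv = np.clip(rv, -1.0, 1.0)
            const = (sxx == 0) | (syy == 0)
            rv[const] = np.nan
            r[idx] = rv
            n_used[idx] = n
            with np.errstate(invalid="ignore", divide="ignore"):
                t = rv * np.sqrt((n - 2) / (1.0 - rv * rv))
            pv = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
            pv[np.abs(rv) == 1.0] = 0.0
            p[idx] = pv
            rest = np.where(testable & ~clean)[0]
        else:
            rest = np.where(testable)[0]
        for j in rest:
            r[j], p[j], n_used[j] = pearson_age_correlation(values[:, j], age)

        degenerate = testable & ~np.isfinite(r)
        reason[degenerate] = "zero_variance"
        tested = np.isfinite(p)

        q = np.full(m, np.nan)
        adjust = bh_adjust if self.multiple_testing == "bh" else bonferroni_adjust
        if tested.any():
            q[tested] = adjust(p[tested])

        selected = tested & (np.abs(r) >= self.min_abs_r) & (q <= self.max_q)
        self.results_ = pd.DataFrame({
            "feature_id": feats, "r": r, "p": p, "q": q, "n_used": n_used,
            "selected": selected, "reason": reason,
        }).set_index("feature_id")
        self.support_ = selected
        self.selected_features_ = [f for f, s in zip(feats, selected) if s]
        self.n_selected_ = int(selected.sum())
        self.n_features_in_ = m
        self.feature_names_in_ = np.asarray(feats, dtype=object)
        n_excl = int((reason != "").sum())
        logger.info("stage=age_screen n_features=%d n_excluded=%d n_selected=%d "
                    "min_abs_r=%g max_q=%g", m, n_excl, self.n_selected_,
                    self.min_abs_r, self.max_q)
        if self.n_selected_ == 0:
            logger.warning("stage=age_screen empty selection; downstream "
                           "model fits will refuse to run")
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_.copy()

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = pd.DataFrame(X)
        missing = [f for f in self.selected_features_ if f not in X.columns]
        if missing:
            raise ValueError(f"X lacks selected features: {missing[:5]}")
        return X[self.selected_features_]


def select_aging_features(assocs: pd.DataFrame, min_abs_r: float,
                          max_q: float) -> list[str]:
    """Apply selection thresholds to a screen results table.

    selected <=> |r| >= min_abs_r and q <= max_q.
    """
    if not (0 <= min_abs_r <= 1) or not (0 <= max_q <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    ok = (assocs["r"].abs() >= min_abs_r) & (assocs["q"] <= max_q)
    ok &= assocs["r"].notna() & assocs["q"].notna()
    selected = assocs.index[ok].tolist()
    logger.info("stage=select_aging min_abs_r=%g max_q=%g n_selected=%d",
                min_abs_r, max_q, len(selected))
    if not selected:
        logger.warning("stage=select_aging empty selection")
    return selected
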