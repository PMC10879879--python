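"""Elastic-net metabolic aging clocks.

The clock regresses chronological age on standardized predictors (pathway
scores for the pathway clock, metabolite intensities for the metabolite
clock) under the elastic-net objective

    (1/2n) ||y - b0 - X b||^2 + lam * (alpha ||b||_1 + (1-alpha)/2 ||b||_2^2)

with mixing parameter ``alpha`` (l1_ratio) and penalty ``lam`` chosen by
K-fold cross-validated mean squared error over a log-spaced grid.  Each
predictor's *importance score* is its standardized-coefficient magnitude
rescaled so the strongest predictor scores 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet, ElasticNetCV, LinearRegression
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger("metaboclock")


# ---------------------------------------------------------------------------
# train/test split


def split_train_test(cohort: pd.DataFrame, fraction: float = 0.75,
                     seed: int = 0) -> pd.Series:
    """Assign healthy subjects to train/test, stratified by sex x age decade.

    Within each stratum, round(fraction * n) subjects go to train (so the
    per-stratum train fraction is within one subject of the target);
    singleton strata go to train.  Deterministic given the seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if "cohort" in cohort.columns and (cohort["cohort"] != "healthy").any():
        raise ValueError("split_train_test expects healthy subjects only")
    rng = np.random.default_rng(seed)
    labels = pd.Series("test", index=cohort.index, name="split")
    decade = (cohort["age"] // 10).astype(int)
    for _, idx in cohort.groupby([cohort["sex"], decade], observed=True).groups.items():
        idx = list(idx)
        if len(idx) == 1:
            labels[idx] = "train"
            logger.info("stage=split singleton stratum -> train: %s", idx)
            continue
        n_train = int(round(fraction * len(idx)))
        order = rng.permutation(len(idx))
        labels[[idx[i] for i in order[:n_train]]] = "train"
    logger.info("stage=split seed=%d n_train=%d n_test=%d", seed,
                (labels == "train").sum(), (labels == "test").sum())
    return labels


# ---------------------------------------------------------------------------
# the clock estimator


class MetabolicAgeClock(RegressorMixin, BaseEstimator):
    """Elastic-net regression of age on standardized predictors.

    Parameters
    ----------
    l1_ratio : float
        Elastic-net mixing parameter alpha in [0, 1] (1 = lasso).
    lam : float or None
        Fixed penalty strength; ``None`` selects it by cross-validation.
        ``lam == 0`` fits ordinary least squares.
    lambda_grid : array-like or None
        Explicit penalty grid for CV; ``None`` uses a data-driven
        ``n_lambdas``-point log grid.
    n_lambdas : int
        Grid size when ``lambda_grid`` is None.
    cv : int
        Number of cross-validation folds.
    random_state : int or None
        Seeds the CV fold shuffle.

    Attributes
    ----------
    predictor_ids_ : list of str
    coef_ : ndarray -- coefficients on the standardized predictor scale
    coef_raw_, intercept_raw_ : back-transformed raw-scale equivalents
    intercept_ : float
    lambda_ : float -- penalty actually used
    importance_ : ndarray -- importance scores, 0..100
    """

    def __init__(self, l1_ratio: float = 0.5, lam: float | None = None,
                 lambda_grid=None, n_lambdas: int = 100, cv: int = 10,
                 random_state: int | None = None, max_iter: int = 50_000,
                 tol: float = 1e-4):
        self.l1_ratio = l1_ratio
        self.lam = lam
        self.lambda_grid = lambda_grid
        self.n_lambdas = n_lambdas
        self.cv = cv
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if len(X) != y.size:
            raise ValueError("X and y length mismatch")
        if len(X) < 2:
            raise ValueError("need at least 2 samples")
        bad = [str(c) for c in X.columns
               if not np.isfinite(X[c].to_numpy(dtype=float)).all()]
        if bad:
            raise ValueError(f"non-finite values in predictor columns: {bad[:5]}")
        if self.lambda_grid is not None and len(self.lambda_grid) == 0:
            raise ValueError("lambda grid is empty")

        self.predictor_ids_ = [str(c) for c in X.columns]
        V = X.to_numpy(dtype=float)
        self.mean_ = V.mean(axis=0)
        self.scale_ = V.std(axis=0, ddof=0)
        if np.any(self.scale_ == 0):
            const = [c for c, s in zip(self.predictor_ids_, self.scale_) if s == 0]
            raise ValueError(f"constant predictor columns: {const[:5]}")
        Z = (V - self.mean_) / self.scale_

        if self.lam is not None and self.lam == 0:
            ols = LinearRegression().fit(Z, y)
            coef, intercept, lam = ols.coef_, float(ols.intercept_), 0.0
        elif self.lam is not None:
            en = ElasticNet(alpha=self.lam, l1_ratio=self.l1_ratio,
                            max_iter=self.max_iter, tol=self.tol).fit(Z, y)
            coef, intercept, lam = en.coef_, float(en.intercept_), float(self.lam)
        else:
            folds = KFold(n_splits=self.cv, shuffle=True,
                          random_state=self.random_state)
            cv_kwargs = dict(l1_ratio=self.l1_ratio, cv=folds,
                             max_iter=self.max_iter, tol=self.tol)
            # sklearn's `alphas` takes either an explicit grid or a grid size
            if self.lambda_grid is not None:
                cv_kwargs["alphas"] = np.asarray(self.lambda_grid, dtype=float)
            else:
                cv_kwargs["alphas"] = self.n_lambdas
            en = ElasticNetCV(**cv_kwargs).fit(Z, y)
            coef, intercept, lam = en.coef_, float(en.intercept_), float(en.alpha_)
            self.cv_lambdas_ = en.alphas_
            self.cv_mse_path_ = en.mse_path_

        self.coef_ = np.asarray(coef, dtype=float)
        self.intercept_ = intercept
        self.lambda_ = lam
        self.coef_raw_ = self.coef_ / self.scale_
        self.intercept_raw_ = self.intercept_ - float(self.coef_raw_ @ self.mean_)
        self.importance_ = importance_scores(self)
        self.n_features_in_ = len(self.predictor_ids_)
        logger.info("stage=fit_clock n=%d p=%d lambda=%.4g nonzero=%d",
                    len(y), self.n_features_in_, lam,
                    int(np.sum(self.coef_ != 0)))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            cols = [str(c) for c in X.columns]
            missing = [c for c in self.predictor_ids_ if c not in cols]
            if missing:
                raise ValueError(f"missing predictor columns: {missing[:5]}")
            extra = [c for c in cols if c not in self.predictor_ids_]
            if extra:
                raise ValueError(
                    f"unexpected extra columns (strict schema): {extra[:5]}")
            V = X[self.predictor_ids_].to_numpy(dtype=float)
        else:
            V = np.asarray(X, dtype=float)
            if V.ndim != 2 or V.shape[1] != len(self.predictor_ids_):
                raise ValueError("X must have exactly the fitted predictors")
        Z = (V - self.mean_) / self.scale_
        return self.intercept_ + Z @ self.coef_

    @property
    def nonzero_predictors_(self) -> list[str]:
        check_is_fitted(self, "coef_")
        return [p for p, b in zip(self.predictor_ids_, self.coef_) if b != 0]

    def to_json(self, path) -> None:
        """Persist the fitted model (coefficients + standardization)."""
        check_is_fitted(self, "coef_")
        import json
        payload = {
            "predictor_ids": self.predictor_ids_,
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "lambda": self.lambda_,
            "l1_ratio": self.l1_ratio,
            "importance": self.importance_.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MetabolicAgeClock":
        import json
        with open(path) as fh:
            d = json.load(fh)
        model = cls(l1_ratio=d["l1_ratio"], lam=d["lambda"])
        model.predictor_ids_ = list(d["predictor_ids"])
        model.coef_ = np.asarray(d["coef"], dtype=float)
        model.intercept_ = float(d["intercept"])
        model.mean_ = np.asarray(d["mean"], dtype=float)
        model.scale_ = np.asarray(d["scale"], dtype=float)
        model.lambda_ = float(d["lambda"])
        model.coef_raw_ = model.coef_ / model.scale_
        model.intercept_raw_ = model.intercept_ - float(
            model.coef_raw_ @ model.mean_)
        model.importance_ = np.asarray(d["importance"], dtype=float)
        model.n_features_in_ = len(model.predictor_ids_)
        return model


def importance_scores(model: MetabolicAgeClock) -> np.ndarray:
    """IS_j = 100 |b_j| / max_k |b_k| on standardized coefficients.

    All-zero models get all-zero scores (with a warning); zero-coefficient
    predictors score 0 and the top predictor scores 100.
    """
    check_is_fitted(model, "coef_")
    mag = np.abs(model.coef_)
    top = mag.max(initial=0.0)
    if top == 0.0:
        logger.warning("stage=importance all coefficients zero")
        return np.zeros_like(mag)
    return 100.0 * mag / top


def fit_elastic_net(X, y, alpha: float = 0.5, lambda_grid=None,
                    cv_folds: int = 10, seed: int | None = None
                    ) -> MetabolicAgeClock:
    """Functional wrapper over :class:`MetabolicAgeClock`."""
    return MetabolicAgeClock(l1_ratio=alpha, lambda_grid=lambda_grid,
                             cv=cv_folds, random_state=seed).fit(X, y)


def predict_age(model: MetabolicAgeClock, X) -> np.ndarray:
    return model.predict(X)


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class ClockEvaluation:
    """Fit quality on one split: Pearson r and predicted-on-actual slope."""

    split: str
    n: int
    r: float
    r_ci: tuple[float, float]
    slope: float
    slope_ci: tuple[float, float]
    degenerate: bool = False


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval: tanh(atanh(r) +/- z / sqrt(n-3))."""
    if n <= 3:
        raise ValueError("Fisher CI requires n > 3")
    z = stats.norm.ppf(0.5 + level / 2)
    half = z / np.sqrt(n - 3)
    center = np.arctanh(r)
    return (float(np.tanh(center - half)), float(np.tanh(center + half)))


def evaluate_clock(pred, actual, split: str = "test") -> ClockEvaluation:
    """Pearson r with Fisher-z 95% CI and the regression slope of predicted
    on actual age with its standard-error CI."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("length mismatch")
    n = pred.size
    if n < 4:
        raise ValueError("need n >= 4")
    if np.std(pred) == 0 or np.std(actual) == 0:
        return ClockEvaluation(split, n, np.nan, (np.nan, np.nan),
                               np.nan, (np.nan, np.nan), degenerate=True)
    r = float(stats.pearsonr(pred, actual).statistic)
    if abs(r) < 1.0:
        r_ci = fisher_ci(r, n)
    else:
        r_ci = (r, r)
    fit = stats.linregress(actual, pred)
    z = stats.norm.ppf(0.975)
    slope_ci = (float(fit.slope - z * fit.stderr),
                float(fit.slope + z * fit.stderr))
    return ClockEvaluation(split, n, r, r_ci, float(fit.slope), slope_ci)


def compare_correlations(evals: list[ClockEvaluation]) -> tuple[float, float]:
    """Fisher-z heterogeneity test across independent-sample correlations.

    Q = sum w_i (z_i - zbar)^2 with w_i = n_i - 3 and zbar the weighted
    mean; Q ~ chi-square on k-1 df under equality.  Returns (Q, p).  With
    two groups this reduces to the standard two-sample z test squared.
    """
    if len(evals) < 2:
        raise ValueError("need >= 2 correlations")
    if any(e.n <= 3 for e in evals):
        raise ValueError("every sample must have n > 3")
    z = np.array([np.arctanh(e.r) for e in evals])
    w = np.array([e.n - 3 for e in evals], dtype=float)
    zbar = (w * z).sum() / w.sum()
    q = float((w * (z - zbar) ** 2).sum())
    p = float(stats.chi2.sf(q, df=len(evals) - 1))
    return q, p
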