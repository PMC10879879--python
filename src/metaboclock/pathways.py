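"""Aggregate age-associated features into per-sample pathway scores.

A pathway's score for one subject is the weighted sum of the subject's
standardized values of the selected features mapped to that pathway,
divided by the number of mapped (retained) features:

    score_p = sum_{i in members_p} w_i * z_i / |members_p|

Standardization parameters (per-feature mean and sd) are estimated once on
a declared reference set -- the healthy training subjects -- and applied
unchanged everywhere else, so diseased and held-out samples are scored on
the healthy scale without leakage.  Default weights are each feature's
Pearson correlation with age: the sign encodes trend direction, the
magnitude encodes strength; uniform weights are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import PathwayMap

logger = logging.getLogger("metaboclock")


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature mean/sd on a declared reference subject set."""

    mean: pd.Series
    sd: pd.Series
    reference_ids: tuple[str, ...]
    dropped: tuple[str, ...] = ()

    def apply(self, X: pd.DataFrame) -> pd.DataFrame:
        feats = self.mean.index
        missing = feats.difference(X.columns).tolist()
        if missing:
            raise ValueError(f"X lacks standardized features: {missing[:5]}")
        return (X[feats] - self.mean) / self.sd


def fit_standardization(features: pd.DataFrame,
                        reference_ids) -> StandardizationParams:
    """Estimate per-feature mean and sd on the reference subjects only.

    Features constant on the reference (sd == 0) are dropped with a log
    entry; applying the result to the reference yields mean 0, sd 1.
    """
    reference_ids = list(reference_ids)
    if not reference_ids:
        raise ValueError("reference set is empty")
    ref = features.loc[reference_ids]
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        logger.warning("stage=standardize reason=zero_variance n_dropped=%d "
                       "features=%s", len(constant), constant[:5])
    keep = sd.index.difference(constant, sort=False)
    return StandardizationParams(mean[keep], sd[keep], tuple(reference_ids),
                                 tuple(constant))


def pathway_score(z: Mapping[str, float], members, weights: Mapping[str, float]
                  ) -> float:
    """Score one subject on one pathway: sum(w_i * z_i) / |mapped members|."""
    mapped = [m for m in members if m in z]
    if not mapped:
        raise ValueError("no pathway members among available features")
    return sum(weights.get(m, 0.0) * z[m] for m in mapped) / len(mapped)


class PathwayScorer(BaseEstimator, TransformerMixin):
    """Transform standardized feature values into pathway scores.

    Parameters
    ----------
    pathway_map : PathwayMap
        Feature membership per pathway.
    weights : mapping feature_id -> weight, or "uniform"
        Per-feature weights; only features with a weight contribute (pass
        the screen's selected features' correlations).  ``"uniform"`` gives
        every selected feature weight 1; in that case ``selected_features``
        must be provided.
    selected_features : list of str, optional
        Explicit selection when ``weights == "uniform"``.

    The reference set for standardization is whatever is passed to ``fit``
    (the healthy training subjects in the pipeline).
    """

    def __init__(self, pathway_map: PathwayMap, weights="uniform",
                 selected_features=None):
        self.pathway_map = pathway_map
        self.weights = weights
        self.selected_features = selected_features

    def _weights_dict(self) -> dict[str, float]:
        if isinstance(self.weights, str):
            if self.weights != "uniform":
                raise ValueError("weights must be a mapping or 'uniform'")
            if self.selected_features is None:
                raise ValueError("uniform weights require selected_features")
            return {f: 1.0 for f in self.selected_features}
        return dict(self.weights)

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        w = self._weights_dict()
        usable = [f for f in w if f in X.columns]
        if not usable:
            raise ValueError("no weighted features present in X")
        self.standardization_ = fit_standardization(X[usable], list(X.index))
        retained = list(self.standardization_.mean.index)
        self.map_ = self.pathway_map.restrict_to(retained)
        if len(self.map_) == 0:
            raise ValueError("no pathway retains a selected feature")
        self.feature_ids_ = retained
        self.pathway_ids_ = list(self.map_.members)
        # loading matrix L[i, p] = w_i / |members_p| for member features
        col = {f: i for i, f in enumerate(retained)}
        L = np.zeros((len(retained), len(self.pathway_ids_)))
        for pj, pid in enumerate(self.pathway_ids_):
            mem = self.map_.members[pid]
            for f in mem:
                L[col[f], pj] = w[f] / len(mem)
        self.loadings_ = L
        self.weights_ = pd.Series({f: w[f] for f in retained})
        logger.info("stage=pathway_scores n_features=%d n_pathways=%d",
                    len(retained), len(self.pathway_ids_))
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "loadings_")
        X = pd.DataFrame(X)
        Z = self.standardization_.apply(X)
        scores = Z.to_numpy(dtype=float) @ self.loadings_
        return pd.DataFrame(scores, index=X.index, columns=self.pathway_ids_)


def score_all(features: pd.DataFrame, pathway_map: PathwayMap,
              selection, weights, params: StandardizationParams
              ) -> pd.DataFrame:
    """Pathway scores for all subjects from precomputed standardization.

    Functional form of :class:`PathwayScorer` for callers that manage their
    own standardization reference; only ``selection`` features contribute.
    """
    if not list(selection):
        raise ValueError("empty feature selection")
    w = ({f: 1.0 for f in selection} if isinstance(weights, str)
         else {f: weights[f] for f in selection})
    usable = [f for f in selection if f in params.mean.index]
    Z = params.apply(features)[usable]
    pmap = pathway_map.restrict_to(usable)
    if len(pmap) == 0:
        raise ValueError("no pathway retains a selected feature")
    col = {f: i for i, f in enumerate(usable)}
    L = np.zeros((len(usable), len(pmap.members)))
    for pj, pid in enumerate(pmap.members):
        mem = pmap.members[pid]
        for f in mem:
            L[col[f], pj] = w[f] / len(mem)
    return pd.DataFrame(Z.to_numpy(dtype=float) @ L, index=features.index,
                        columns=list(pmap.members))
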