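"""End-to-end orchestration of the metabolic aging-clock analysis.

``run_pipeline`` strings the stages together on in-memory tables:

1. stratified 75/25 split of healthy subjects;
2. age-association screen of all features on the healthy training set;
3. pathway scores (correlation weights, training-set standardization) and
   the pathway-level elastic-net clock;
4. the metabolite-level clock on the identified biomarker panel;
5. delta age for every subject, subgroup thresholds from the healthy test
   split, subgroup fractions per cohort at the configured quantile pair;
6. screening PPVs for APL and CRC at population incidence, with and
   without the CEA multi-target filter;
7. mutation enrichment in stage I CRC.

The permutation-null check lives in :mod:`metaboclock.inference` and is
run separately (it refits the pipeline many times).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clock import ClockEvaluation, MetabolicAgeClock, evaluate_clock, split_train_test
from .delta import DeltaAgeClassifier, compute_delta, subgroup_fractions
from .io import PathwayMap, PipelineConfig, align_cohort_features, stage_seed
from .pathways import PathwayScorer
from .screen import AgeCorrelationScreen
from .screening import ScreenConfig, ScreenResult, run_screen
from .simulate import CLOCK_METABOLITES
from .inference import mutation_enrichment

logger = logging.getLogger("metaboclock")


@dataclass
class PipelineResult:
    """Everything the pipeline computed, keyed by stage."""

    split: pd.Series
    screen: AgeCorrelationScreen
    pathway_scorer: PathwayScorer | None
    pathway_clock: MetabolicAgeClock | None
    pathway_eval: dict[str, ClockEvaluation]
    metabolite_clock: MetabolicAgeClock
    metabolite_eval: dict[str, ClockEvaluation]
    delta: pd.Series
    subgroups: pd.Series
    thresholds: tuple[float, float]
    cohort_fractions: pd.DataFrame
    screen_results: dict[str, ScreenResult] = field(default_factory=dict)
    enrichment: pd.DataFrame | None = None


def run_pipeline(cohort: pd.DataFrame, features: pd.DataFrame,
                 pathway_map: PathwayMap | None,
                 config: PipelineConfig | None = None,
                 sex: str | None = None,
                 fit_pathway_clock: bool = True) -> PipelineResult:
    """Run the full analysis; see module docstring for the stage list.

    ``sex`` restricts the whole analysis to one sex (the sex-stratified
    fits) -- same code path on a subset.
    """
    config = config or PipelineConfig()
    if sex is not None:
        cohort = cohort[cohort["sex"] == sex]
    cohort, features = align_cohort_features(cohort, features)

    healthy = cohort[cohort["cohort"] == "healthy"]
    if healthy.empty:
        raise ValueError("no healthy subjects: cannot fit the clock")
    split = split_train_test(healthy, config.train_fraction,
                             stage_seed(config.seed, "split"))
    train_ids = split.index[split == "train"]
    test_ids = split.index[split == "test"]
    y_train = healthy.loc[train_ids, "age"]
    y_test = healthy.loc[test_ids, "age"]

    # --- univariate screen on healthy training subjects --------------------
    screen = AgeCorrelationScreen(
        min_abs_r=config.min_abs_r, max_q=config.max_q,
        multiple_testing=config.multiple_testing,
        min_completeness=config.min_completeness,
    ).fit(features.loc[train_ids], y_train)
    if screen.n_selected_ == 0:
        raise ValueError("age screen selected no features; refusing to fit")
    selected = screen.selected_features_

    # --- pathway clock ------------------------------------------------------
    pathway_scorer = None
    pathway_clock = None
    pathway_eval: dict[str, ClockEvaluation] = {}
    if fit_pathway_clock and pathway_map is not None:
        weights = (screen.results_.loc[selected, "r"].to_dict()
                   if config.pathway_weights == "correlation"
                   else "uniform")
        pathway_scorer = PathwayScorer(pathway_map, weights=weights,
                                       selected_features=selected)
        pathway_scorer.fit(features.loc[train_ids])
        scores_train = pathway_scorer.transform(features.loc[train_ids])
        scores_test = pathway_scorer.transform(features.loc[test_ids])
        pathway_clock = MetabolicAgeClock(
            l1_ratio=config.l1_ratio, n_lambdas=config.n_lambdas,
            cv=config.cv_folds,
            random_state=stage_seed(config.seed, "pathway-clock"),
        ).fit(scores_train, y_train)
        pathway_eval = {
            "train": evaluate_clock(pathway_clock.predict(scores_train),
                                    y_train, "train"),
            "test": evaluate_clock(pathway_clock.predict(scores_test),
                                   y_test, "test"),
        }

    # --- metabolite clock on the identified biomarker panel -----------------
    identified = (list(config.identified_metabolites)
                  if config.identified_metabolites is not None
                  else list(CLOCK_METABOLITES))
    panel = [m for m in identified if m in features.columns]
    if not panel:
        raise ValueError("none of the identified metabolites are measured")
    metabolite_clock = MetabolicAgeClock(
        l1_ratio=config.l1_ratio, n_lambdas=config.n_lambdas,
        cv=config.cv_folds,
        random_state=stage_seed(config.seed, "metabolite-clock"),
    ).fit(features.loc[train_ids, panel], y_train)
    metabolite_eval = {
        "train": evaluate_clock(
            metabolite_clock.predict(features.loc[train_ids, panel]),
            y_train, "train"),
        "test": evaluate_clock(
            metabolite_clock.predict(features.loc[test_ids, panel]),
            y_test, "test"),
    }

    # --- delta age and subgroups --------------------------------------------
    pred_all = pd.Series(
        metabolite_clock.predict(features[panel]), index=features.index)
    delta = pd.Series(compute_delta(pred_all, cohort["age"]),
                      index=features.index, name="delta")
    ref_ids = (test_ids if config.threshold_reference == "test"
               else healthy.index)
    clf = DeltaAgeClassifier(config.q_lo, config.q_hi)
    clf.fit(delta.loc[ref_ids], cohort.loc[ref_ids, "cohort"])
    subgroups = pd.Series(clf.predict(delta), index=delta.index,
                          name="subgroup")
    fractions = subgroup_fractions(subgroups, cohort["cohort"],
                                   B=config.subgroup_bootstrap,
                                   seed=stage_seed(config.seed, "fractions"))

    # --- screening PPVs -----------------------------------------------------
    screen_results: dict[str, ScreenResult] = {}
    has_diseased = (cohort["cohort"] != "healthy").any()
    if has_diseased:
        for target, incidence in (("APL", config.apl_incidence),
                                  ("CRC_all_stages", config.crc_incidence)):
            for use_cea, label in ((False, "clock"), (True, "multitarget")):
                cfg = ScreenConfig(
                    target=target, incidence=incidence,
                    coverage=config.coverage,
                    cea_cutoff_nonsmoker=config.cea_cutoff_nonsmoker,
                    cea_cutoff_smoker=config.cea_cutoff_smoker,
                    use_cea_filter=use_cea, missing_cea=config.missing_cea,
                    seed=stage_seed(config.seed, f"screen-{target}-{label}"))
                try:
                    screen_results[f"{target}:{label}"] = run_screen(
                        subgroups, cohort, split, cfg)
                except ValueError as exc:
                    logger.warning("stage=crc_screen target=%s skipped: %s",
                                   target, exc)

    # --- mutation enrichment ------------------------------------------------
    enrichment = None
    mut_cols = [m for m in ("kras", "nras", "braf") if m in cohort.columns]
    if mut_cols and (cohort["cohort"] == "CRC_I").any():
        enrichment = mutation_enrichment(
            subgroups, cohort, mutations=mut_cols,
            B=config.enrichment_bootstrap,
            seed=stage_seed(config.seed, "enrichment"))

    return PipelineResult(
        split=split, screen=screen, pathway_scorer=pathway_scorer,
        pathway_clock=pathway_clock, pathway_eval=pathway_eval,
        metabolite_clock=metabolite_clock, metabolite_eval=metabolite_eval,
        delta=delta, subgroups=subgroups, thresholds=clf.thresholds_,
        cohort_fractions=fractions, screen_results=screen_results,
        enrichment=enrichment)
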