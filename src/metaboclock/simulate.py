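"""Synthetic serum-metabolomics cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without any external data:

* a healthy reference population plus advanced-precancerous-lesion (APL)
  and stage I-III colorectal cancer (CRC) cohorts, with decade age-bin and
  sex proportions matching the study demographics;
* ~1,603 metabolic features of which 157 carry linear age trends with
  prescribed Pearson correlations; the rest are pure noise;
* nine named clock metabolites with literature-consistent trend signs
  (kynurenine and phenylalanine rise with age, DHEA-sulfate falls, ...);
* a "hypo-aging" mechanism: diseased subjects' aging features are generated
  from an *effective* age equal to chronological age minus a nonnegative
  shift, so their metabolome looks younger than they are;
* serum CEA with elevation enriched in CRC, and KRAS/NRAS/BRAF mutation
  flags in stage I CRC at the study prevalences, mutants carrying an extra
  hypo shift.

Intensities live on a log-like additive scale; downstream stages
standardize per feature, so the absolute scale is immaterial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import COHORTS, CRC_COHORTS, MUTATIONS, PathwayMap

# Decade age bins and per-cohort subject counts mirroring the study's
# demographics table; sampling probabilities are the row proportions.
AGE_BINS = ((30, 40), (40, 50), (50, 60), (60, 70), (70, 80), (80, 90))
AGE_BIN_COUNTS = {
    "healthy": (21, 503, 1124, 851, 387, 116),
    "APL": (14, 105, 219, 268, 90, 19),
    "CRC_I": (12, 148, 295, 426, 175, 32),
    "CRC_II": (9, 55, 104, 161, 80, 18),
    "CRC_III": (17, 60, 123, 138, 66, 13),
}
COHORT_SIZES = {"healthy": 3002, "APL": 715, "CRC_I": 1088,
                "CRC_II": 427, "CRC_III": 417}
MALE_FRACTION = {"healthy": 0.437, "APL": 0.573, "CRC_I": 0.573,
                 "CRC_II": 0.637, "CRC_III": 0.561}

#: The nine clock metabolites: trend sign and target |r| with age.  Signs
#: follow the serum-aging literature (kynurenine, phenylalanine, citrulline,
#: ornithine, citrate, 3-(4-hydroxyphenyl)lactate, gulonate and
#: prolylleucine increase with age; DHEA-sulfate declines).  Targets sit
#: above the background aging-feature range so the clock metabolites are the
#: strongest univariate signals, as a curated biomarker panel would be.
CLOCK_METABOLITES = {
    "kynurenine": (+1, 0.75),
    "phenylalanine": (+1, 0.70),
    "DHEA-sulfate": (-1, 0.70),
    "citrulline": (+1, 0.65),
    "citrate": (+1, 0.65),
    "3-(4-hydroxyphenyl)lactate": (+1, 0.60),
    "ornithine": (+1, 0.60),
    "gulonate": (+1, 0.55),
    "prolylleucine": (+1, 0.50),
}

_SUBJECT_PREFIX = {"healthy": "H", "APL": "A", "CRC_I": "C1",
                   "CRC_II": "C2", "CRC_III": "C3"}


@dataclass
class SimulationSpec:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    n_per_cohort: dict[str, int] = field(
        default_factory=lambda: dict(COHORT_SIZES))
    age_bin_probs: dict[str, tuple[float, ...]] | None = None  # None -> demographics table
    male_fraction: dict[str, float] = field(
        default_factory=lambda: dict(MALE_FRACTION))
    n_features: int = 1603
    n_aging: int = 157
    aging_r_range: tuple[float, float] = (0.10, 0.28)
    clock_metabolites: dict[str, tuple[int, float]] = field(
        default_factory=lambda: dict(CLOCK_METABOLITES))
    # disease model: effective age = age - shift, shift ~ max(0, N(mean, sd))
    hypo_shift: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"APL": (8.0, 4.0), "CRC_I": (8.0, 4.0),
                                 "CRC_II": (8.0, 4.0), "CRC_III": (8.0, 4.0)})
    mutation_prevalence: dict[str, float] = field(
        default_factory=lambda: {"kras": 0.398, "nras": 0.034, "braf": 0.044})
    n_mutation_profiled: int | None = 412   # stage I subjects with mutation calls
    mutant_extra_shift: float = 4.0
    # serum CEA (ug/L): lognormal baseline with a cohort-dependent chance of
    # drawing from an elevated component
    cea_elevation_prob: dict[str, float] = field(
        default_factory=lambda: {"healthy": 0.08, "APL": 0.15, "CRC_I": 0.35,
                                 "CRC_II": 0.50, "CRC_III": 0.60})
    cea_baseline: tuple[float, float] = (np.log(1.5), 0.6)   # log-location, log-scale
    cea_elevated: tuple[float, float] = (np.log(12.0), 0.6)
    smoker_p: float = 0.25
    noise_sd: float = 1.0
    n_pathways: int = 40
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_aging > self.n_features:
            raise ValueError("n_aging must be <= n_features")
        if self.n_aging < len(self.clock_metabolites):
            raise ValueError("n_aging must cover the clock metabolites")
        for name, (sign, r) in self.clock_metabolites.items():
            if sign not in (-1, +1):
                raise ValueError(f"trend sign for {name} must be +1 or -1")
            if not 0 < r < 1:
                raise ValueError(f"target |r| for {name} must be in (0, 1)")
        probs = list(self.mutation_prevalence.values())
        probs += list(self.cea_elevation_prob.values()) + [self.smoker_p,
                                                           self.missing_rate]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must be in [0, 1]")
        lo, hi = self.aging_r_range
        if not 0 < lo <= hi < 1:
            raise ValueError("aging_r_range must satisfy 0 < lo <= hi < 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery tests.

    ``features``: per-feature is_aging / is_clock flags, trend sign, target
    |r| and realized slope.  ``subjects``: per-subject hypo shift and
    effective metabolic age (equal to chronological age for healthy
    subjects).
    """

    features: pd.DataFrame
    subjects: pd.DataFrame

    def to_json(self, path: str | Path) -> None:
        payload = {
            "features": self.features.reset_index().to_dict(orient="list"),
            "subjects": self.subjects.reset_index().to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        feats = pd.DataFrame(payload["features"]).set_index("feature_id")
        subs = pd.DataFrame(payload["subjects"]).set_index("subject_id")
        return cls(feats, subs)


# ---------------------------------------------------------------------------
# primitives


def age_slope(target_r: float, noise_sd: float, age_sd: float) -> float:
    """Slope giving Pearson correlation ``target_r`` for x = a*age + noise.

    From r = a*sd_age / sqrt(a^2 sd_age^2 + noise_sd^2):
    a = sign(r) * |r|/sqrt(1-r^2) * noise_sd/sd_age.
    """
    if abs(target_r) >= 1:
        raise ValueError("|target_r| must be < 1")
    if noise_sd <= 0 and target_r != 0:
        raise ValueError(
            "noise_sd must be > 0 when |target_r| < 1; with zero noise the "
            "empirical correlation is +/-1 regardless of the target")
    if age_sd <= 0:
        raise ValueError("ages must have nonzero variance")
    if target_r == 0:
        return 0.0
    return (np.sign(target_r) * abs(target_r) / np.sqrt(1 - target_r**2)
            * noise_sd / age_sd)


def simulate_feature(ages, target_r: float, noise_sd: float,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """One feature vector with a linear age trend at the target correlation."""
    ages = np.asarray(ages, dtype=float)
    if ages.size < 3:
        raise ValueError("need >= 3 ages")
    sd = float(np.std(ages, ddof=1))
    slope = age_slope(target_r, noise_sd, sd)  # validates r, noise_sd, sd
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return slope * ages + rng.normal(0.0, noise_sd, size=ages.size)


def draw_mutation_flags(n: int, prevalence: dict[str, float],
                        rng: np.random.Generator) -> pd.DataFrame:
    """Independent Bernoulli mutation flags at the given prevalences."""
    return pd.DataFrame(
        {m: rng.random(n) < p for m, p in prevalence.items()}
    ).astype("boolean")


# ---------------------------------------------------------------------------
# cohort generator


def _draw_ages(cohort: str, n: int, spec: SimulationSpec,
               rng: np.random.Generator) -> np.ndarray:
    if spec.age_bin_probs is not None and cohort in spec.age_bin_probs:
        probs = np.asarray(spec.age_bin_probs[cohort], dtype=float)
    else:
        probs = np.asarray(AGE_BIN_COUNTS[cohort], dtype=float)
    probs = probs / probs.sum()
    bins = rng.choice(len(AGE_BINS), size=n, p=probs)
    lo = np.array([AGE_BINS[b][0] for b in bins], dtype=float)
    hi = np.array([AGE_BINS[b][1] for b in bins], dtype=float)
    return lo + rng.random(n) * (hi - lo)


def simulate_cohort(
    spec: SimulationSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, PathwayMap, GroundTruth]:
    """Generate (cohort table, feature matrix, pathway map, ground truth).

    Deterministic for a fixed spec and seed.  Aging features are
    ``baseline + slope * effective_age + N(0, noise_sd)`` with the slope
    solved analytically from the target correlation and the healthy
    population's age variance; non-aging features are pure noise.
    """
    spec = spec or SimulationSpec()
    root = np.random.SeedSequence(spec.seed)
    rngs = {name: np.random.default_rng(ss) for name, ss in zip(
        ("cohort", "shift", "mutation", "features", "cea", "pathways", "missing"),
        root.spawn(7))}

    # --- clinical axis -----------------------------------------------------
    rows = []
    for cohort in COHORTS:
        n = int(spec.n_per_cohort.get(cohort, 0))
        if n == 0:
            continue
        rng = rngs["cohort"]
        ages = _draw_ages(cohort, n, spec, rng)
        male = rng.random(n) < spec.male_fraction.get(cohort, 0.5)
        smoker = rng.random(n) < spec.smoker_p
        prefix = _SUBJECT_PREFIX[cohort]
        ids = [f"{prefix}{i:05d}" for i in range(n)]
        block = pd.DataFrame({
            "subject_id": ids,
            "age": ages,
            "sex": np.where(male, "male", "female"),
            "cohort": cohort,
            "smoker": smoker,
        })
        rows.append(block)
    cohort_df = pd.concat(rows, ignore_index=True).set_index("subject_id")
    cohort_df["smoker"] = cohort_df["smoker"].astype("boolean")
    n_total = len(cohort_df)

    # --- mutations (profiled stage I CRC subset only) -----------------------
    for m in MUTATIONS:
        cohort_df[m] = pd.array([pd.NA] * n_total, dtype="boolean")
    c1_ids = cohort_df.index[cohort_df["cohort"] == "CRC_I"]
    n_prof = (len(c1_ids) if spec.n_mutation_profiled is None
              else min(spec.n_mutation_profiled, len(c1_ids)))
    profiled = rngs["mutation"].choice(len(c1_ids), size=n_prof, replace=False)
    prof_ids = c1_ids[np.sort(profiled)]
    flags = draw_mutation_flags(n_prof, spec.mutation_prevalence,
                                rngs["mutation"])
    for m in MUTATIONS:
        if m in flags:
            cohort_df.loc[prof_ids, m] = flags[m].to_numpy(dtype=bool)

    # --- hypo-aging shift ---------------------------------------------------
    shift = np.zeros(n_total)
    for cohort, (mean, sd) in spec.hypo_shift.items():
        mask = (cohort_df["cohort"] == cohort).to_numpy()
        if mask.any():
            draw = rngs["shift"].normal(mean, sd, size=mask.sum())
            shift[mask] = np.maximum(0.0, draw)
    any_mut = np.zeros(n_total, dtype=bool)
    for m in MUTATIONS:
        any_mut |= cohort_df[m].fillna(False).to_numpy(dtype=bool)
    shift[any_mut] += spec.mutant_extra_shift
    effective_age = cohort_df["age"].to_numpy() - shift

    # --- CEA ----------------------------------------------------------------
    rng = rngs["cea"]
    mu0, s0 = spec.cea_baseline
    mu1, s1 = spec.cea_elevated
    p_elev = cohort_df["cohort"].map(spec.cea_elevation_prob).fillna(0.0)
    elevated = rng.random(n_total) < p_elev.to_numpy()
    log_cea = np.where(elevated, rng.normal(mu1, s1, n_total),
                       rng.normal(mu0, s0, n_total))
    cohort_df["cea"] = np.exp(log_cea)

    # --- molecular axis -----------------------------------------------------
    clock_names = list(spec.clock_metabolites)
    n_bg_aging = spec.n_aging - len(clock_names)
    bg_aging_ids = [f"F{i:04d}" for i in range(n_bg_aging)]
    noise_ids = [f"F{i:04d}" for i in range(n_bg_aging,
                                            spec.n_features - len(clock_names))]
    feature_ids = clock_names + bg_aging_ids + noise_ids

    rng = rngs["features"]
    healthy_ages = cohort_df.loc[cohort_df["cohort"] == "healthy", "age"]
    age_sd = float(healthy_ages.std(ddof=1)) if len(healthy_ages) > 1 else float(
        cohort_df["age"].std(ddof=1))

    lo, hi = spec.aging_r_range
    target_r = np.zeros(spec.n_features)
    signs = np.ones(spec.n_features)
    for j, name in enumerate(clock_names):
        sign, r = spec.clock_metabolites[name]
        target_r[j] = r
        signs[j] = sign
    k = len(clock_names)
    target_r[k:k + n_bg_aging] = rng.uniform(lo, hi, n_bg_aging)
    signs[k:k + n_bg_aging] = rng.choice([-1.0, 1.0], n_bg_aging)

    slopes = np.array([
        age_slope(s * r, spec.noise_sd, age_sd) if r > 0 else 0.0
        for s, r in zip(signs, target_r)
    ])
    baselines = rng.normal(10.0, 2.0, spec.n_features)
    values = (baselines[None, :]
              + np.outer(effective_age, slopes)
              + rng.normal(0.0, spec.noise_sd, size=(n_total, spec.n_features)))
    features_df = pd.DataFrame(values, index=cohort_df.index,
                               columns=feature_ids)

    if spec.missing_rate > 0:
        mask = rngs["missing"].random(features_df.shape) < spec.missing_rate
        features_df = features_df.mask(mask)

    # --- synthetic pathway map ---------------------------------------------
    rng = rngs["pathways"]
    aging_ids = clock_names + bg_aging_ids
    members: dict[str, set[str]] = {f"SP{i:02d}": set()
                                    for i in range(spec.n_pathways)}
    for i, fid in enumerate(aging_ids):
        members[f"SP{i % spec.n_pathways:02d}"].add(fid)
        if rng.random() < 0.3:  # KEGG-style multi-membership
            members[f"SP{rng.integers(spec.n_pathways):02d}"].add(fid)
    pmap = PathwayMap({p: frozenset(m) for p, m in members.items() if m},
                      {p: f"synthetic pathway {p}" for p in members if members[p]})

    # --- ground truth -------------------------------------------------------
    is_aging = np.zeros(spec.n_features, dtype=bool)
    is_aging[:spec.n_aging] = True
    truth_features = pd.DataFrame({
        "feature_id": feature_ids,
        "is_aging": is_aging,
        "is_clock": [fid in spec.clock_metabolites for fid in feature_ids],
        "sign": signs,
        "target_r": target_r * signs,
        "slope": slopes,
    }).set_index("feature_id")
    truth_subjects = pd.DataFrame({
        "shift": shift,
        "effective_age": effective_age,
    }, index=cohort_df.index)
    truth = GroundTruth(truth_features, truth_subjects)

    return cohort_df, features_df, pmap, truth
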