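"""Generator contracts: determinism, target correlations, ground truth."""

import numpy as np
import pandas as pd
import pytest

from metaboclock import SimulationSpec, simulate_cohort, simulate_feature
from metaboclock.simulate import CLOCK_METABOLITES, draw_mutation_flags

from conftest import SMALL_SPEC


class TestSimulateFeature:
    def test_zero_target_r_is_pure_noise(self):
        ages = np.linspace(30, 80, 100)
        x = simulate_feature(ages, 0.0, noise_sd=1.0, seed=1)
        # slope exactly zero: subtracting the noise leaves nothing age-linked
        x2 = simulate_feature(ages, 0.0, noise_sd=1.0, seed=1)
        assert np.array_equal(x, x2)
        assert abs(np.corrcoef(x, ages)[0, 1]) < 0.3

    def test_zero_noise_with_partial_target_rejected(self):
        ages = np.linspace(30, 80, 10)
        with pytest.raises(ValueError, match="noise_sd"):
            simulate_feature(ages, 0.9, noise_sd=0.0)

    @pytest.mark.parametrize("bad_r", [1.0, -1.0, 1.5])
    def test_unit_target_rejected(self, bad_r):
        with pytest.raises(ValueError):
            simulate_feature(np.linspace(30, 80, 10), bad_r, 1.0)

    def test_degenerate_ages_rejected(self):
        with pytest.raises(ValueError):
            simulate_feature([50.0, 50.0, 50.0], 0.4, 1.0)
        with pytest.raises(ValueError):
            simulate_feature([50.0, 60.0], 0.4, 1.0)

    def test_empirical_r_hits_target_at_large_n(self):
        # Fisher-z sampling tolerance at n=5000 is ~3/sqrt(n-3) ~ 0.042
        rng = np.random.default_rng(11)
        ages = rng.normal(55, 10, 5000)
        x = simulate_feature(ages, 0.4, noise_sd=1.0, seed=5)
        r = np.corrcoef(x, ages)[0, 1]
        assert 0.37 <= r <= 0.43

    def test_negative_target_gives_negative_trend(self):
        rng = np.random.default_rng(2)
        ages = rng.normal(55, 10, 5000)
        x = simulate_feature(ages, -0.5, noise_sd=1.0, seed=3)
        assert np.corrcoef(x, ages)[0, 1] < -0.45


class TestSimulateCohort:
    def test_reproducible_bit_identical(self):
        spec = SimulationSpec(**SMALL_SPEC)
        c1, f1, p1, t1 = simulate_cohort(spec)
        c2, f2, p2, t2 = simulate_cohort(SimulationSpec(**SMALL_SPEC))
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(f1, f2)
        assert p1.members == p2.members
        pd.testing.assert_frame_equal(t1.subjects, t2.subjects)

    def test_zero_shift_means_effective_equals_chronological(self):
        kw = dict(SMALL_SPEC)
        kw["hypo_shift"] = {c: (0.0, 0.0) for c in
                            ("APL", "CRC_I", "CRC_II", "CRC_III")}
        kw["mutant_extra_shift"] = 0.0
        cohort, _, _, truth = simulate_cohort(SimulationSpec(**kw))
        np.testing.assert_allclose(truth.subjects["effective_age"],
                                   cohort["age"])
        assert (truth.subjects["shift"] == 0).all()

    def test_healthy_subjects_never_shifted(self, small_sim):
        cohort, _, _, truth = small_sim
        healthy = cohort.index[cohort["cohort"] == "healthy"]
        assert (truth.subjects.loc[healthy, "shift"] == 0).all()
        assert (truth.subjects.loc[cohort.index[cohort["cohort"] != "healthy"],
                                   "shift"] >= 0).all()

    def test_cohort_sizes_and_schema(self, small_sim):
        cohort, features, pmap, truth = small_sim
        assert cohort["cohort"].value_counts().to_dict() == {
            "healthy": 600, "CRC_I": 300, "APL": 150, "CRC_II": 80,
            "CRC_III": 80}
        assert features.shape == (len(cohort), 300)
        assert list(features.index) == list(cohort.index)
        assert set(CLOCK_METABOLITES) <= set(features.columns)

    def test_clock_metabolite_trend_signs(self, small_sim):
        cohort, features, _, _ = small_sim
        healthy = cohort["cohort"] == "healthy"
        age = cohort.loc[healthy, "age"]
        for name, (sign, target) in CLOCK_METABOLITES.items():
            r = np.corrcoef(features.loc[healthy, name], age)[0, 1]
            assert np.sign(r) == sign, name
            assert abs(r) > 0.5 * target, name

    def test_empirical_r_within_fisher_band_at_n2000(self, healthy_sim):
        # n=2000 healthy: empirical r within ~0.05 of the target for the
        # strongest clock metabolite (Fisher sd ~ 1/sqrt(n-3) ~ 0.022)
        cohort, features, _, truth = healthy_sim
        age = cohort["age"]
        for name in ("kynurenine", "phenylalanine"):
            target = CLOCK_METABOLITES[name][1]
            r = abs(np.corrcoef(features[name], age)[0, 1])
            assert abs(r - target) < 0.05, name

    def test_mutations_only_in_profiled_stage1(self, small_sim):
        cohort, _, _, _ = small_sim
        flagged = cohort[["kras", "nras", "braf"]].notna().any(axis=1)
        assert (cohort.loc[flagged, "cohort"] == "CRC_I").all()
        assert int(cohort["kras"].notna().sum()) == 200  # profiled subset

    def test_mutation_prevalence_matches_study_rates(self):
        # mean mutant counts over 200 seeded draws of 412 profiled subjects
        # should sit within 2 binomial sd of 164 / 14 / 18
        prev = {"kras": 0.398, "nras": 0.034, "braf": 0.044}
        counts = {m: [] for m in prev}
        for seed in range(200):
            flags = draw_mutation_flags(412, prev,
                                        np.random.default_rng(seed))
            for m in prev:
                counts[m].append(int(flags[m].sum()))
        for m, expected in (("kras", 164), ("nras", 14), ("braf", 18)):
            mean = np.mean(counts[m])
            sd = np.sqrt(412 * prev[m] * (1 - prev[m])) / np.sqrt(200)
            assert abs(mean - expected) < 2 * max(sd, 1.0), m

    def test_cea_elevation_enriched_in_crc(self, small_sim):
        cohort, _, _, _ = small_sim
        frac = cohort.groupby("cohort", observed=True)["cea"].apply(
            lambda s: (s > 5.0).mean())
        assert frac["CRC_I"] > frac["healthy"]
        assert frac["CRC_III"] > frac["healthy"]

    def test_every_pathway_contains_an_aging_feature(self, small_sim):
        _, _, pmap, truth = small_sim
        aging = set(truth.features.index[truth.features["is_aging"]])
        for pid, members in pmap.members.items():
            assert members & aging, pid

    def test_truth_json_round_trip(self, small_sim, tmp_path):
        _, _, _, truth = small_sim
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = type(truth).from_json(path)
        pd.testing.assert_frame_equal(back.subjects, truth.subjects)
        pd.testing.assert_frame_equal(back.features, truth.features)

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec(n_features=100, n_aging=200)
        with pytest.raises(ValueError):
            SimulationSpec(noise_sd=0.0)
        with pytest.raises(ValueError):
            SimulationSpec(mutation_prevalence={"kras": 1.4})
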