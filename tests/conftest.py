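import logging

import numpy as np
import pandas as pd
import pytest

from metaboclock import SimulationSpec, simulate_cohort

logging.getLogger("metaboclock").setLevel(logging.ERROR)


SMALL_SPEC = dict(
    n_per_cohort={"healthy": 600, "APL": 150, "CRC_I": 300,
                  "CRC_II": 80, "CRC_III": 80},
    n_features=300,
    n_aging=40,
    n_mutation_profiled=200,
    seed=42,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully structured cohort shared across tests."""
    return simulate_cohort(SimulationSpec(**SMALL_SPEC))


@pytest.fixture(scope="session")
def healthy_sim():
    """A healthy-only cohort for clock/threshold tests."""
    spec = SimulationSpec(
        n_per_cohort={"healthy": 2000}, n_features=200, n_aging=30, seed=7)
    return simulate_cohort(spec)


@pytest.fixture
def toy_cohort():
    return pd.DataFrame({
        "subject_id": ["s1", "s2", "s3", "s4", "s5", "s6"],
        "age": [45.0, 60.0, 72.0, 55.0, 49.0, 66.0],
        "sex": ["male", "female", "male", "female", "male", "female"],
        "cohort": ["healthy", "healthy", "healthy", "healthy", "CRC_I", "APL"],
        "smoker": [False, True, False, False, True, False],
        "cea": [1.2, 2.5, 0.8, 11.0, 30.0, 4.0],
    }).set_index("subject_id")


@pytest.fixture
def rng():
    return np.random.default_rng(123)
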