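import numpy as np
import pytest

from secondhit import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Three simulated patients at default study conditions (seeded)."""
    config = CohortConfig(n_patients=3, seed=42)
    patients, truths, signatures = simulate_cohort(config)
    return config, patients, truths, signatures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
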