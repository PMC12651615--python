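import numpy as np
import pytest

from presage import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-person, 28-day cohort used by several integration tests."""
    return simulate_cohort(CohortConfig(n_participants=12, n_days=28, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
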