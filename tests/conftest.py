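import pytest

from trialcea.cohort import CohortConfig, generate_cohort
from trialcea.costing import default_cost_weights
from trialcea.projection import default_life_table


@pytest.fixture(scope="session")
def weights():
    return default_cost_weights()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def small_cohort():
    """Default-calibration cohort, 150 patients per arm."""
    return generate_cohort(CohortConfig(n_per_arm=150, seed=11))


@pytest.fixture(scope="session")
def large_cohort():
    """Default-calibration cohort, 2000 patients per arm (direction checks)."""
    return generate_cohort(CohortConfig(n_per_arm=2000, seed=7))
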