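import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glycoserum.cohort import CohortConfig, reference_panel, simulate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return reference_panel()


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded cohort at the default study conditions (75 UC + 75 HLT)."""
    return simulate_cohort(CohortConfig(seed=20130))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort, still large enough for the Bonferroni screen to
    find glycans in both directions."""
    return simulate_cohort(CohortConfig(n_uc=60, n_hlt=60, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
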