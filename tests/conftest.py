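import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from nephrometry import SimConfig, derive_variables, simulate_cohort  # noqa: E402


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(SimConfig(seed=0))


@pytest.fixture(scope="session")
def derived(default_cohort):
    return derive_variables(default_cohort)
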