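import pytest
from hypothesis import HealthCheck, settings

from tabsim import bundled_country, default_risk_parameters, generate_country

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def risk():
    return default_risk_parameters()


@pytest.fixture
def ar():
    return bundled_country("ar")


@pytest.fixture(scope="session")
def synth():
    """A synthetic country with known truth (seed 5)."""
    return generate_country(seed=5)
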