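import pytest
from hypothesis import HealthCheck, settings

import riverhealth as rh

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry() -> rh.IndicatorRegistry:
    return rh.default_registry()


@pytest.fixture(scope="session")
def fixture_bundle() -> rh.LhasaFixture:
    return rh.lhasa_fixture()


@pytest.fixture(scope="session")
def default_panel(registry):
    """Synthetic 3-station x 4-year panel plus the intended score matrix."""
    scenario = rh.SyntheticScenario(seed=7)
    observations, intended = rh.generate_panel(scenario, registry)
    return scenario, observations, intended
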