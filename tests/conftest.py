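import pytest
from hypothesis import HealthCheck, settings

from telovasc.config import ScenarioConfig, scenario_null
from telovasc.sim import simulate_study

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_config() -> ScenarioConfig:
    """A small null scenario shared by the slower fixtures."""
    return scenario_null(n=150, seed=11, n_cpgs=200, n_causal_cpgs=2)


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return simulate_study(tiny_config)
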