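import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from finwalk import Arena, ModelParams, SimulationConfig, run_simulation

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20140843)


@pytest.fixture
def arena():
    return Arena(side=120.0, corner_radius=10.0)


@pytest.fixture(scope="session")
def default_run():
    """One walker run with the calibrated global bundle, shared across tests."""
    cfg = SimulationConfig(duration=600.0, seed=7)
    return run_simulation(ModelParams.default(), cfg), cfg
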