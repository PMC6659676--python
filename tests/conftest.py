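import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from costimnet import (
    Condition,
    SimulationSettings,
    apply_condition,
    default_model,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture
def dual(model):
    return apply_condition(model, Condition.from_treatment("dual"))


@pytest.fixture
def quick_settings():
    return SimulationSettings(p=0.5, max_steps=120, horizon=30, n_runs=25, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
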