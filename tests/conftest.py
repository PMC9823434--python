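import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mstaf import (
    CommunityState,
    SuccessionScenario,
    SyntheticSample,
    default_group_models,
    default_protocols,
    simulate_succession,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return default_protocols()


@pytest.fixture(scope="session")
def group_models():
    return default_group_models()


@pytest.fixture
def mixed_sample():
    """A mid-season mixed community (cyanobacteria-dominated)."""
    states = simulate_succession(SuccessionScenario(seed=11))
    return SyntheticSample(state=states[12])


@pytest.fixture
def algae_only_sample():
    state = CommunityState(0, {"algae": 8000.0, "cyanobacteria": 0.0})
    return SyntheticSample(state=state)


@pytest.fixture
def cyano_only_sample():
    state = CommunityState(0, {"algae": 0.0, "cyanobacteria": 15000.0})
    return SyntheticSample(state=state)


@pytest.fixture
def blank_sample():
    state = CommunityState(0, {"algae": 0.0, "cyanobacteria": 0.0})
    return SyntheticSample(state=state)
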