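import numpy as np
import pytest

from fourstep.planner import PlannerParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def base_params():
    return PlannerParams()


@pytest.fixture
def quiet_params():
    """Noise-free, drop-free, lapse-free planner for deterministic checks."""
    return PlannerParams(noise_sd=0.0, delta=0.0, lapse=0.0)
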