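import numpy as np
import pytest

from venofluct import BloodModel
from venofluct.synth import SimulationScenario


@pytest.fixture
def model():
    """Default 1.5-T venous blood model (Y=0.66, C1=59 1/s, TE=30 ms)."""
    return BloodModel()


@pytest.fixture
def quiet_scenario():
    """Noiseless, motion-free study scenario with all defaults."""
    return SimulationScenario(noise_sd=0.0, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
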