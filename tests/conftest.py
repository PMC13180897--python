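import numpy as np
import pytest

from istroop import generate_schedule
from istroop.simulate import SimulationConfig


@pytest.fixture(scope="session")
def default_schedule():
    return generate_schedule(0)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
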