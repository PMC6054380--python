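import numpy as np
import pytest

from ecocredit import EconomyParams, EnvironmentParams, toy_world
from ecocredit.simulation import initialize


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def env():
    return EnvironmentParams(grid_rows=10, grid_cols=10)


@pytest.fixture
def econ():
    return EconomyParams()


@pytest.fixture
def toy_config():
    return toy_world()


@pytest.fixture
def toy_state(toy_config):
    return initialize(toy_config, seed=3)
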