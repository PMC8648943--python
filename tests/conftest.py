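import numpy as np
import pytest

from bondscape import BondModel, CurveSynthesisSpec, Environment


@pytest.fixture
def env():
    return Environment()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def inserted_bond(env):
    """Bond parameters of the membrane-inserted state (52 ms contact time)."""
    return BondModel(k0=2.0, x_beta=0.81, env=env)


@pytest.fixture
def clamp_bond(env):
    """Bond parameters from the height-clamp lifetime analysis."""
    return BondModel(k0=1.0 / 0.32, x_beta=0.57, env=env)


@pytest.fixture
def curve_spec(env):
    return CurveSynthesisSpec(env=env)
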