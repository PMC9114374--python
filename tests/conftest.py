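import numpy as np
import pytest

from neurongrowth import bspline_collocation as bsc
from neurongrowth import growth_model as gm


@pytest.fixture(scope="session")
def grid32():
    return bsc.build_collocation_grid(32, 32)


@pytest.fixture(scope="session")
def grid64():
    return bsc.build_collocation_grid(64, 64)


@pytest.fixture()
def params():
    return gm.ModelParameters()


@pytest.fixture()
def circle_state(params, grid64):
    return gm.initialize_state(params, [(32.0, 32.0)], grid64)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
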