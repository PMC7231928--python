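import numpy as np
import pytest

from zsted import make_preset


@pytest.fixture
def confocal_vol():
    return make_preset("confocal")


@pytest.fixture
def zsted_vol():
    return make_preset("z_sted")


@pytest.fixture
def sted2d_vol():
    return make_preset("2d_sted")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
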