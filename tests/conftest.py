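import numpy as np
import pytest

from smoothgame import SmoothingSpec, mec_game, td_game


@pytest.fixture
def k10():
    return SmoothingSpec(10.0)


@pytest.fixture
def td_r02_k10(k10):
    return td_game(0.2, k10)


@pytest.fixture
def mec_c03_k10(k10):
    return mec_game(0.3, k10)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
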