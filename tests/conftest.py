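import numpy as np
import pytest

from fruitethanol import SensorModel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def mos_model():
    return SensorModel.mos(seed=7)


@pytest.fixture
def gc_model():
    return SensorModel.gc(seed=7)


@pytest.fixture
def cr2_model():
    return SensorModel.cr2(seed=7)
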