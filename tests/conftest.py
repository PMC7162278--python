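import numpy as np
import pytest

from lungtcm import Calibration, FractionMap, HUVolume

AIR_PU = Calibration(113.4, -999.5, ("PU", "air"))
AIR_MUSCLE = Calibration(50.7, -999.3, ("muscle", "air"))


@pytest.fixture
def rng():
    return np.random.default_rng(20231108)


@pytest.fixture
def air_pu_cal():
    return AIR_PU


@pytest.fixture
def air_muscle_cal():
    return AIR_MUSCLE


@pytest.fixture
def constant_volume():
    def make(value, shape=(4, 5, 6), spacing=(1.0, 1.0, 1.0)):
        return HUVolume(np.full(shape, float(value)), spacing)

    return make


@pytest.fixture
def random_fraction_map(rng):
    def make(shape=(8, 9, 10), spacing=(1.0, 1.0, 1.0)):
        return FractionMap(rng.random(shape), spacing)

    return make
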