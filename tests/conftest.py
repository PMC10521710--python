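import numpy as np
import pytest

from virtualher2 import synth


@pytest.fixture(scope="session")
def geom_small():
    return synth.GeometryParams(height=128, width=128)


@pytest.fixture(scope="session")
def geom_mid():
    return synth.GeometryParams(height=256, width=256)


@pytest.fixture(scope="session")
def pair_grade3(geom_mid):
    return synth.simulate_pair(3, geometry=geom_mid, seed=11)


@pytest.fixture(scope="session")
def pair_grade2(geom_mid):
    return synth.simulate_pair(2, geometry=geom_mid, seed=12)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
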