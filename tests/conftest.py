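import numpy as np
import pytest

from vesised.geometry import compute_geometry
from vesised.mesh import build_icosphere, make_spheroid


@pytest.fixture(scope="session")
def ico1():
    return build_icosphere(1)


@pytest.fixture(scope="session")
def ico2():
    return build_icosphere(2)


@pytest.fixture(scope="session")
def ico3():
    return build_icosphere(3)


@pytest.fixture(scope="session")
def geom3(ico3):
    return compute_geometry(ico3)


@pytest.fixture(scope="session")
def spheroid15():
    return make_spheroid(1.5, 3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20131107)
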