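import numpy as np
import pytest

from nodescale.geometry import spherocylinder
from nodescale.steady import ModificationModelParams, UniformModelParams
from nodescale.spatial import SpatialModelParams


@pytest.fixture
def geom_short():
    """Newborn-sized wild-type cell (L = 7 um) with a 3-um nodal band."""
    return spherocylinder(7.0, 1.5, 3.0)


@pytest.fixture
def geom_long():
    """Division-sized wild-type cell (L = 14 um) with a 3-um nodal band."""
    return spherocylinder(14.0, 1.5, 3.0)


@pytest.fixture
def params1_const():
    """Model I defaults with a strictly constant cytoplasmic concentration."""
    return UniformModelParams(cyt_slope=0.0)


@pytest.fixture
def params2():
    return ModificationModelParams()


@pytest.fixture
def sparams():
    return SpatialModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
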