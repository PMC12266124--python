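import numpy as np
import pytest

from mtukit.fem import ActuationSpec, MaterialParams
from mtukit.mesh import box_mesh


@pytest.fixture(scope="session")
def uniform_bar():
    """2 x 2 x 10 mm homogeneous bar, every element contractile."""
    return box_mesh(2.0, 2.0, 10.0, 0.5, contractile="all")


@pytest.fixture(scope="session")
def materials():
    return MaterialParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
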