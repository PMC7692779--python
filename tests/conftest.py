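import numpy as np
import pytest

from knotdrift.free_energy import default_params, get_knot


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def trefoil():
    return get_knot("3_1")


@pytest.fixture
def cinquefoil():
    return get_knot("5_1")


@pytest.fixture
def params_tensionless(trefoil):
    return default_params("3_1", tension=0.0)
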