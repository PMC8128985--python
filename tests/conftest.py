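import numpy as np
import pytest
from hypothesis import settings

import netkin as nk
from netkin import dialect as dia

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def grid100():
    return nk.SpatialGrid.uniform(100)


@pytest.fixture
def dialect_params():
    return dia.DialectParams(M=2, alpha_exp=2.0, gamma=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_node_network():
    """Two nodes coupled with unit weight, no self-weight, unit density."""
    return nk.NodeNetwork(np.array([[0.0, 1.0], [1.0, 0.0]]))
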