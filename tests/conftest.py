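import numpy as np
import pytest

from kurnet.meanfield import single_node_critical_coupling


@pytest.fixture(scope="session")
def K_c():
    """Single-node critical coupling of the standard normal density."""
    return single_node_critical_coupling()


@pytest.fixture()
def two_node_bi():
    return np.array([[0.0, 1.0], [1.0, 0.0]])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
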