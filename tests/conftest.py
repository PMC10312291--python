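import numpy as np
import pytest

from epispread import BrainNetwork


@pytest.fixture
def path3():
    """Unit-weight path A-B-C."""
    w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
    return BrainNetwork(w, node_labels=["A", "B", "C"])


@pytest.fixture
def star5():
    """Unit-weight star K_{1,4}; node 0 is the hub."""
    w = np.zeros((5, 5))
    w[0, 1:] = w[1:, 0] = 1.0
    return BrainNetwork(w)


@pytest.fixture
def triangle():
    w = np.ones((3, 3)) - np.eye(3)
    return BrainNetwork(w)


@pytest.fixture
def small_edr():
    from epispread import make_edr_network
    net, pos = make_edr_network(n=40, rng_seed=11)
    return net, pos
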