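import numpy as np
import pytest

from pgsom.core import NetworkState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_network(weights, positions, mode="gsom", eta=0.3, dim=None):
    """Hand-build a network from parallel weight/position lists."""
    weights = [np.asarray(w, dtype=float) for w in weights]
    dim = dim if dim is not None else len(weights[0])
    state = NetworkState(dim=dim, mode=mode, eta=eta)
    for w, pos in zip(weights, positions):
        state.add_neuron(tuple(pos), w)
    return state


@pytest.fixture
def block3x3():
    """3x3 fully occupied block on [0,2]^2; weights = grid coordinates."""
    positions = [(r, c) for r in range(3) for c in range(3)]
    weights = [np.array([float(r), float(c)]) for r, c in positions]
    return build_network(weights, positions)


@pytest.fixture
def two_cluster_data(rng):
    """Seeded 2-D two-cluster dataset used by growth smoke tests."""
    a = rng.normal(loc=(-3.0, 0.0), scale=0.3, size=(150, 2))
    b = rng.normal(loc=(3.0, 0.0), scale=0.3, size=(150, 2))
    X = np.vstack([a, b])
    y = np.repeat([1, 2], 150)
    perm = rng.permutation(len(X))
    return X[perm], y[perm]
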