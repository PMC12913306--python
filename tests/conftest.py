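import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_dag_weights(d, rng, density=0.4, low=0.5, high=2.0):
    """Random acyclic weight matrix: upper-triangular support under a random
    permutation, weights bounded away from zero."""
    upper = np.triu(rng.random((d, d)) < density, k=1)
    W = np.where(
        upper,
        rng.uniform(low, high, (d, d)) * rng.choice([-1.0, 1.0], (d, d)),
        0.0,
    )
    perm = rng.permutation(d)
    return W[np.ix_(perm, perm)]


def central_difference(f, W, eps=1e-6):
    """Entrywise central finite differences of a scalar function of W."""
    G = np.zeros_like(W)
    for i in range(W.shape[0]):
        for j in range(W.shape[1]):
            Wp = W.copy()
            Wp[i, j] += eps
            Wm = W.copy()
            Wm[i, j] -= eps
            G[i, j] = (f(Wp) - f(Wm)) / (2 * eps)
    return G
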