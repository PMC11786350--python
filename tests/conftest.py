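import numpy as np
import pytest

from fastdeconv import SpotGeometry, build_graph


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_geometry(m, seed, with_z=True):
    g = np.random.default_rng(seed)
    return SpotGeometry(
        spot_ids=np.array([f"s{i}" for i in range(m)]),
        x=g.uniform(0, 10, m),
        y=g.uniform(0, 10, m),
        z=g.uniform(0, 1, m) if with_z else None,
    )


def random_graph(m, seed, k=5):
    return build_graph(random_geometry(m, seed), k=min(k, m - 1))


@pytest.fixture
def small_graph():
    return random_graph(12, seed=7, k=3)


@pytest.fixture
def planted_factorization():
    """Well-separated rank-2 factorization with disjoint marker blocks."""
    g = np.random.default_rng(42)
    n, m, r = 30, 20, 2
    W = np.zeros((n, r))
    W[:15, 0] = g.uniform(1, 2, 15)
    W[15:, 1] = g.uniform(1, 2, 15)
    H = g.dirichlet((2, 2), size=m)
    return W, H, W @ H.T
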