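import numpy as np
import pytest
import scipy.sparse as sp

from crosschat.graph import CellGraph
from crosschat.io import ExpressionMatrix, LRDatabase, LRInteraction, LOGNORM, RAW_COUNTS


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_counts():
    """6 cells x 4 genes raw counts with simple structure."""
    vals = np.array(
        [
            [4, 0, 1, 2],
            [9, 1, 0, 2],
            [0, 4, 4, 2],
            [1, 9, 9, 2],
            [0, 0, 4, 2],
            [2, 1, 9, 2],
        ],
        dtype=float,
    )
    return ExpressionMatrix(
        vals, ["Liga", "Recb", "Ligc", "Hk"], [f"c{i}" for i in range(6)], RAW_COUNTS
    )


@pytest.fixture
def toy_db():
    return LRDatabase(
        [
            LRInteraction("Liga", "Recb", "PW1"),
            LRInteraction("Ligc", "Recb", "PW1"),
            LRInteraction("Igf2", "Itga6_Itgb4", "IGF"),
        ]
    )


@pytest.fixture
def two_clique_graph():
    """Two 10-node cliques joined by a unit-weight bridge."""
    n = 20
    a = np.zeros((n, n))
    a[:10, :10] = 1.0
    a[10:, 10:] = 1.0
    np.fill_diagonal(a, 0.0)
    a[9, 10] = a[10, 9] = 1.0
    return CellGraph([f"c{i}" for i in range(n)], sp.csr_matrix(a))


def random_partition(rng, n, max_k):
    """Uniform random labeling with at most max_k blocks."""
    k = rng.integers(1, max_k + 1)
    lab = rng.integers(0, k, size=n)
    return lab


@pytest.fixture
def lognorm_toy(toy_counts):
    from crosschat.io import lognormalize

    return lognormalize(toy_counts)
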