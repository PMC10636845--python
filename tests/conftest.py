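import numpy as np
import pytest

from tsclust.data import ExpressionMatrix
from tsclust.graph import CellGraph
from tsclust.walk import walk_profile


def graph_from_weights(w: np.ndarray) -> CellGraph:
    """CellGraph from an explicit symmetric weight matrix (tests only)."""
    w = np.asarray(w, dtype=float)
    return CellGraph(node_ids=[f"c{i}" for i in range(w.shape[0])],
                     weights=w, metric_name="test")


def profile_from_weights(w, t=4):
    return walk_profile(graph_from_weights(w), t=t)


def two_clique_weights(n_per=3, strong=1.0, weak=0.05) -> np.ndarray:
    """Two equal-weight cliques joined by a single weak edge."""
    n = 2 * n_per
    w = np.zeros((n, n))
    for block in (range(n_per), range(n_per, n)):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = strong
    w[n_per - 1, n_per] = w[n_per, n_per - 1] = weak
    return w


@pytest.fixture
def expr_small():
    """4 cells x 3 genes, plain nonnegative values."""
    values = np.array([[1.0, 0.0, 2.0],
                       [2.0, 1.0, 0.0],
                       [0.0, 3.0, 1.0],
                       [1.0, 1.0, 1.0]])
    return ExpressionMatrix(values)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
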