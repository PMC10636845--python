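"""Random walks on the core-cell graph and the random-walk distance.

A walker on the core-cell graph moves with transition probabilities
``M_ij = w_ij / Deg(i)``.  After ``t`` steps the row vector ``P_i.^t``
(= row i of M^t) summarises cell i's position in the graph topology:
cells embedded in the same dense region see similar t-step landscapes.
The random-walk distance between cells i and j is the degree-weighted
L2 distance between their probability rows

    d_ij = sqrt( sum_k (P_ik^t - P_jk^t)^2 / Deg(k) ).

``t`` trades locality against mixing: too small and the walk has not seen
the neighbourhood structure, too large and every row approaches the
stationary distribution (which depends only on Deg) so all distances
collapse to zero.  The default is t = 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data import TsclustError
from .graph import CellGraph

DEFAULT_WALK_STEPS = 4


@dataclass
class WalkProfile:
    """t-step walk probabilities for every core cell.

    ``probs[i, k]`` is the probability of reaching core cell k from core
    cell i in exactly ``t`` steps; each row sums to 1.  ``degrees`` are the
    weighted degrees of the core-cell graph (the same Deg used by the
    transition matrix and by the random-walk distance).
    """

    probs: np.ndarray
    degrees: np.ndarray
    t: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.degrees = np.asarray(self.degrees, dtype=float)
        if self.probs.shape[0] != self.probs.shape[1]:
            raise TsclustError("walk-probability matrix must be square")
        if self.degrees.shape != (self.probs.shape[0],):
            raise TsclustError("degree vector length mismatch")
        if np.any(self.degrees <= 0):
            raise TsclustError("isolated node in core graph")

    @property
    def n(self) -> int:
        return self.probs.shape[0]


def transition_matrix(g_cc: CellGraph) -> np.ndarray:
    """Row-stochastic transition matrix M_ij = w_ij / Deg(i), zero diagonal."""
    if g_cc.n_nodes == 0:
        raise TsclustError("empty core graph")
    deg = g_cc.degrees()
    if np.any(deg <= 0):
        raise TsclustError("isolated node in core graph")
    return g_cc.weights / deg[:, None]


def walk_probabilities(m: np.ndarray, degrees: np.ndarray,
                       t: int = DEFAULT_WALK_STEPS) -> WalkProfile:
    """Evolve every start distribution e_i for ``t`` steps; rows of M^t.

    ``t = 0`` returns the identity (the walker has not moved), not an error.
    """
    m = np.asarray(m, dtype=float)
    if t < 0:
        raise TsclustError("t must be nonnegative")
    probs = np.linalg.matrix_power(m, t)
    return WalkProfile(probs=probs, degrees=degrees, t=t)


def walk_profile(g_cc: CellGraph, t: int = DEFAULT_WALK_STEPS) -> WalkProfile:
    """Convenience: transition matrix + t-step walk on a core-cell graph."""
    return walk_probabilities(transition_matrix(g_cc), g_cc.degrees(), t)


def rw_distance(p: WalkProfile) -> np.ndarray:
    """Pairwise random-walk distance matrix (symmetric, zero diagonal)."""
    scaled = p.probs / np.sqrt(p.degrees)[None, :]
    return squareform(pdist(scaled, metric="euclidean"))
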