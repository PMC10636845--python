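"""Cell-cell similarity graphs and core-cell selection.

Cells become nodes of a fully connected weighted graph whose edge weights
are similarities in [0, 1] under one of five metrics:

* ``ed`` / ``md`` — Euclidean / Manhattan distance mapped to similarity by
  ``s = 1 - d / d_max`` (``d_max`` the largest pairwise distance);
* ``pcc`` / ``scc`` — Pearson / Spearman correlation with negative values
  clamped to 0 (only positive correlation counts as similarity);
* ``snn`` — shared-nearest-neighbour overlap ``|kNN(i) ∩ kNN(j)| / k`` with
  Euclidean k-nearest neighbourhoods that exclude the cell itself.

Core cells are found by keeping only the strongest edges: sort all
m(m-1)/2 weights, retain the top ``edge_fraction`` (default 25%, ties at
the cut included), and call every cell incident to a retained edge *core*.
Cells whose every similarity falls below the cut are *non-core* — they sit
near cluster boundaries and are assigned only in the second clustering step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from sklearn.neighbors import NearestNeighbors

from .data import ExpressionMatrix, TsclustError

METRICS = ("ed", "md", "pcc", "scc", "snn")
DEFAULT_EDGE_FRACTION = 0.25
DEFAULT_SNN_K = 20


@dataclass
class CellGraph:
    """Weighted undirected graph over cells.

    ``weights`` is the dense symmetric m x m similarity matrix with zero
    diagonal; a zero off-diagonal entry means the edge is absent.
    """

    node_ids: list[str]
    weights: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.node_ids), len(self.node_ids)):
            raise TsclustError("weight matrix shape does not match node count")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def degrees(self) -> np.ndarray:
        """Weighted degree Deg(i) = sum_j w_ij over neighbours (no self-loop)."""
        return self.weights.sum(axis=1)


@dataclass
class CoreSplit:
    """Partition of cells into core and non-core by edge thresholding."""

    core_cell_ids: list[str]
    noncore_cell_ids: list[str]
    s_c: float
    retained_edge_count: int
    edge_fraction: float
    core_index: np.ndarray = None  # type: ignore[assignment]  # positions in the full graph
    noncore_index: np.ndarray = None  # type: ignore[assignment]


def _correlation_similarity(values: np.ndarray, method: str) -> np.ndarray:
    if method == "scc":  # Spearman = Pearson on within-cell ranks
        values = scipy.stats.rankdata(values, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.asarray(corr, dtype=float)
    if np.isnan(corr).any():
        warnings.warn(
            "constant cell vector: correlation undefined for some pairs, "
            "similarity set to 0", stacklevel=3)
        corr = np.nan_to_num(corr, nan=0.0)
    return np.clip(corr, 0.0, 1.0)


def _distance_similarity(values: np.ndarray, metric: str) -> np.ndarray:
    d = squareform(pdist(values, metric="euclidean" if metric == "ed" else "cityblock"))
    d_max = d.max()
    if d_max == 0:
        return np.ones_like(d)
    return 1.0 - d / d_max


def _snn_similarity(values: np.ndarray, k: int) -> np.ndarray:
    m = values.shape[0]
    if k >= m:
        raise TsclustError("snn_k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(values)
    idx = nn.kneighbors(values, return_distance=False)
    # drop self wherever it appears in the neighbour list
    member = np.zeros((m, m), dtype=bool)
    for i in range(m):
        neigh = [j for j in idx[i] if j != i][:k]
        member[i, neigh] = True
    shared = member.astype(float) @ member.astype(float).T
    return shared / k


def pairwise_similarity(
    x: ExpressionMatrix, metric: str = "pcc", snn_k: int = DEFAULT_SNN_K
) -> CellGraph:
    """Fully connected similarity graph over the cells of ``x``."""
    metric = metric.lower()
    if metric not in METRICS:
        raise TsclustError(f"unknown metric {metric!r}; choose from {METRICS}")
    if x.n_cells < 2:
        raise TsclustError("need at least 2 cells to build a graph")
    if metric in ("ed", "md"):
        w = _distance_similarity(x.values, metric)
    elif metric in ("pcc", "scc"):
        w = _correlation_similarity(x.values, metric)
    else:
        w = _snn_similarity(x.values, snn_k)
    w = (w + w.T) / 2.0  # enforce exact symmetry against fp asymmetries
    np.fill_diagonal(w, 0.0)
    return CellGraph(node_ids=list(x.cell_ids), weights=w, metric_name=metric)


def select_core_cells(
    g: CellGraph, edge_fraction: float = DEFAULT_EDGE_FRACTION
) -> tuple[CellGraph, CoreSplit]:
    """Threshold the graph to its strongest edges and split cells.

    Keeps the top ``ceil(edge_fraction * E)`` of the E = m(m-1)/2 edge
    weights, plus any edge tied with the weight at the cut (deterministic,
    order-independent).  Zero-weight pairs are never edges.  Returns the
    thresholded core-cell graph (restricted to core cells) and the split.
    """
    if not 0.0 < edge_fraction <= 1.0:
        raise TsclustError("edge_fraction must be in (0, 1]")
    m = g.n_nodes
    iu = np.triu_indices(m, k=1)
    w = g.weights[iu]
    if np.all(w <= 0):
        raise TsclustError("graph has no positive-weight edges")
    n_keep = math.ceil(edge_fraction * w.size)
    order = np.sort(w)[::-1]
    s_c = order[n_keep - 1]
    if s_c <= 0:
        # the nominal cut falls inside the zero-weight block; absent edges
        # cannot be retained, so the effective cut is the weakest real edge
        warnings.warn("edge-fraction cut reaches zero-weight pairs; only "
                      "positive-weight edges are retained", stacklevel=2)
        s_c = np.min(w[w > 0])
    if np.all(w == w[0]):
        warnings.warn("all edge weights equal; every edge retained", stacklevel=2)
    keep = g.weights >= s_c
    np.fill_diagonal(keep, False)
    retained = int(keep[iu].sum())
    core_mask = keep.any(axis=1)
    core_index = np.flatnonzero(core_mask)
    noncore_index = np.flatnonzero(~core_mask)
    w_cc = np.where(keep, g.weights, 0.0)[np.ix_(core_index, core_index)]
    g_cc = CellGraph(node_ids=[g.node_ids[i] for i in core_index],
                     weights=w_cc, metric_name=g.metric_name)
    split = CoreSplit(
        core_cell_ids=[g.node_ids[i] for i in core_index],
        noncore_cell_ids=[g.node_ids[i] for i in noncore_index],
        s_c=float(s_c),
        retained_edge_count=retained,
        edge_fraction=float(edge_fraction),
        core_index=core_index,
        noncore_index=noncore_index,
    )
    return g_cc, split
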