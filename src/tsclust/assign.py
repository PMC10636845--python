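"""Second clustering step: cluster centers and nearest-center assignment.

After the core cells are clustered, each cluster's center is the per-gene
arithmetic mean of its core cells' (preprocessed) expression rows

    c_kj = sum_{x_c in chi_k} x_cj / |chi_k|

and every non-core cell joins the cluster whose center is nearest in the
same expression space (Euclidean by default, 1 - Pearson optionally for
correlation-built graphs).  Assignment happens once; centers are not
refined afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data import ExpressionMatrix, TsclustError

ASSIGN_METRICS = ("euclidean", "pcc")


@dataclass
class TSCResult:
    """Final per-cell clustering.

    ``labels`` holds one cluster id in 1..k per cell (core and non-core),
    ``is_core`` flags the cells clustered in the first step, and
    ``centers`` is the k x p matrix of cluster centers in preprocessed
    expression space.
    """

    labels: np.ndarray
    k: int
    is_core: np.ndarray
    centers: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.is_core = np.asarray(self.is_core, dtype=bool)
        if not ((self.labels >= 1) & (self.labels <= self.k)).all():
            raise TsclustError("labels must lie in 1..k")


def compute_centers(x: ExpressionMatrix, core_index: np.ndarray,
                    core_labels: np.ndarray) -> np.ndarray:
    """Per-gene mean expression of each cluster's core cells.

    ``core_index`` gives the row positions of the core cells in ``x``;
    ``core_labels`` their 1-based cluster labels.  Row k-1 of the result is
    the center of cluster k.
    """
    core_index = np.asarray(core_index, dtype=int)
    core_labels = np.asarray(core_labels, dtype=int)
    if core_index.size == 0:
        raise TsclustError("no core cells")
    k = int(core_labels.max())
    centers = np.empty((k, x.n_genes))
    for lab in range(1, k + 1):
        rows = core_index[core_labels == lab]
        if rows.size == 0:
            raise TsclustError(f"empty cluster {lab}")
        centers[lab - 1] = x.values[rows].mean(axis=0)
    return centers


def _center_distances(points: np.ndarray, centers: np.ndarray,
                      metric: str) -> np.ndarray:
    if metric == "euclidean":
        return cdist(points, centers)
    if metric == "pcc":
        pc = points - points.mean(axis=1, keepdims=True)
        cc = centers - centers.mean(axis=1, keepdims=True)
        pn = np.linalg.norm(pc, axis=1, keepdims=True)
        cn = np.linalg.norm(cc, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (pc / pn) @ (cc / cn).T
        return 1.0 - np.nan_to_num(corr, nan=0.0)
    raise TsclustError(f"unknown assignment metric {metric!r}")


def assign_noncore(
    x: ExpressionMatrix,
    centers: np.ndarray,
    core_index: np.ndarray,
    core_labels: np.ndarray,
    noncore_index: np.ndarray,
    metric: str = "euclidean",
) -> TSCResult:
    """Assign each non-core cell to its nearest cluster center.

    Core-cell labels are carried through untouched; distance ties go to the
    smallest cluster id, so assignment is independent of cell order.
    """
    if centers.shape[0] == 0:
        raise TsclustError("no clusters to assign to")
    core_index = np.asarray(core_index, dtype=int)
    noncore_index = np.asarray(noncore_index, dtype=int)
    if np.intersect1d(core_index, noncore_index).size:
        raise TsclustError("core and non-core cells overlap")
    labels = np.zeros(x.n_cells, dtype=int)
    labels[core_index] = core_labels
    if noncore_index.size:
        d = _center_distances(x.values[noncore_index], centers, metric)
        labels[noncore_index] = d.argmin(axis=1) + 1  # argmin takes first = smallest id
    is_core = np.zeros(x.n_cells, dtype=bool)
    is_core[core_index] = True
    return TSCResult(labels=labels, k=centers.shape[0], is_core=is_core,
                     centers=centers, cell_ids=list(x.cell_ids))
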