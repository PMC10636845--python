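"""External clustering-agreement scores.

The adjusted Rand index is computed from the true-vs-predicted contingency
table

    ARI = ( sum_ij C(t_ij,2) - [sum_i C(a_i,2) sum_j C(b_j,2)] / C(m,2) )
          / ( [sum_i C(a_i,2) + sum_j C(b_j,2)]/2
              - [sum_i C(a_i,2) sum_j C(b_j,2)] / C(m,2) )

where a_i / b_j are the table's row/column sums and m the number of cells;
it is 1 for identical partitions (up to label renaming), ~0 for random
agreement and can be negative for systematic disagreement.  NMI (arithmetic
normalisation), AMI and best-matching accuracy complement it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_mutual_info_score, normalized_mutual_info_score

from .data import TsclustError


@dataclass
class ContingencyTable:
    """True-vs-predicted cluster overlap counts with margins."""

    counts: np.ndarray
    row_sums: np.ndarray
    col_sums: np.ndarray
    m: int


def contingency_table(labels_true, labels_pred) -> ContingencyTable:
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    if labels_true.shape != labels_pred.shape or labels_true.ndim != 1:
        raise TsclustError("label vectors must be 1-D and of equal length")
    if labels_true.size < 2:
        raise TsclustError("need at least 2 cells to score a clustering")
    _, ti = np.unique(labels_true, return_inverse=True)
    _, pi = np.unique(labels_pred, return_inverse=True)
    counts = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(counts, (ti, pi), 1)
    return ContingencyTable(counts=counts, row_sums=counts.sum(axis=1),
                            col_sums=counts.sum(axis=0), m=int(counts.sum()))


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x * (x - 1) / 2.0


def adjusted_rand_index(labels_true, labels_pred) -> float:
    """ARI straight from the contingency-table formula (see module doc)."""
    tab = contingency_table(labels_true, labels_pred)
    sum_ij = _comb2(tab.counts).sum()
    sum_a = _comb2(tab.row_sums).sum()
    sum_b = _comb2(tab.col_sums).sum()
    expected = sum_a * sum_b / _comb2(np.array(tab.m))
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        # both partitions trivial (all singletons or one block): perfect
        # agreement by convention when the index also degenerates
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def matching_accuracy(labels_true, labels_pred) -> float:
    """Best one-to-one cluster-to-class matching accuracy (Hungarian)."""
    tab = contingency_table(labels_true, labels_pred)
    r, c = linear_sum_assignment(tab.counts, maximize=True)
    return float(tab.counts[r, c].sum() / tab.m)


def clustering_scores(labels_true, labels_pred) -> dict[str, float]:
    """ARI, NMI (arithmetic normalisation), AMI and matching accuracy."""
    contingency_table(labels_true, labels_pred)  # validates inputs
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    return {
        "ari": adjusted_rand_index(labels_true, labels_pred),
        "nmi": float(normalized_mutual_info_score(
            labels_true, labels_pred, average_method="arithmetic")),
        "ami": float(adjusted_mutual_info_score(labels_true, labels_pred)),
        "acc": matching_accuracy(labels_true, labels_pred),
    }
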