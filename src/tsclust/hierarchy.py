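"""Bottom-up hierarchical clustering of core cells under random-walk geometry.

Starting from singletons, the pair of clusters whose merge least increases
the average intra-cluster squared distance

    sigma_K = (1/n) sum_clusters sum_{k in C} d_Ck^2

is merged at every step (a Ward-style criterion), recording the merge cost

    delta_sigma(Ci, Cj) = (1/n) ( sum_{k in Cu} d_Cu k^2
                                  - sum_{k in Ci} d_Ci k^2
                                  - sum_{k in Cj} d_Cj k^2 ),   Cu = Ci u Cj

and sigma_K at every level.  Two readings of the cell-to-cluster quantity
d_Ck are provided:

* ``walktrap`` (default): d_Ck is the degree-weighted L2 distance between
  the cluster's averaged probability row P_C. = (1/|C|) sum_{i in C} P_i.
  and the cell's row P_k. — the cluster-level analogue of the random-walk
  distance, and the reading under which delta_sigma is a genuine Ward
  criterion (it reduces to the Lance-Williams closed form
  |Ci||Cj|/(|Ci|+|Cj|) * ||P_Ci - P_Cj||_Deg^2 / n).
* ``literal``: d_Ck = (1/|C|) sum_{i in C} P_ik, the plain average of
  reaching probabilities.  Exposed for comparison; note a probability
  average is large for *close* cells, so the merge objective is not a
  proper distance criterion in this mode.

The number of clusters is chosen where the merge-cost profile jumps:
eta_K = (sigma_{K-1} - sigma_K) / (sigma_K - sigma_{K+1}) compares the cost
of merging K -> K-1 clusters with the cost of the preceding merge, and the
K maximising eta_K (the level just before the first expensive merge) is
selected.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data import TsclustError
from .walk import WalkProfile

MODES = ("walktrap", "literal")
DEFAULT_K_MIN = 2
DEFAULT_K_MAX_CAP = 50


@dataclass
class ClusterState:
    """Full merge history of an agglomerative run over n core cells.

    ``merge_trace`` lists (cluster_a, cluster_b, delta_sigma) triples in
    merge order, cluster ids being the smallest member index of each
    cluster.  ``sigma_history[K]`` holds sigma_K for K = n .. 1.
    ``partition`` maps each core cell to its cluster id at the finest
    recorded level (updated to the selected level by the pipeline).
    """

    n: int
    mode: str
    merge_trace: list[tuple[int, int, float]]
    sigma_history: np.ndarray
    partition: dict[int, int] = field(default_factory=dict)

    def labels_at(self, k: int) -> np.ndarray:
        """Cluster labels (1..k, numbered by smallest member index) at level k."""
        if not 1 <= k <= self.n:
            raise TsclustError(f"level k={k} outside [1, {self.n}]")
        parent = np.arange(self.n)

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b, _ in self.merge_trace[: self.n - k]:
            ra, rb = find(a), find(b)
            parent[max(ra, rb)] = min(ra, rb)
        roots = np.array([find(i) for i in range(self.n)])
        ids = np.unique(roots)
        lookup = {root: lab for lab, root in enumerate(ids, start=1)}
        return np.array([lookup[r] for r in roots])

    def partition_at(self, k: int) -> dict[int, int]:
        labels = self.labels_at(k)
        return {i: int(lab) for i, lab in enumerate(labels)}


def _check_cluster(members) -> np.ndarray:
    members = np.asarray(members, dtype=int)
    if members.size == 0:
        raise TsclustError("empty cluster")
    return members


def cluster_cell_distance(c, k: int, p: WalkProfile, mode: str = "walktrap") -> float:
    """Cell-to-cluster quantity d_Ck under the chosen reading (see module doc)."""
    members = _check_cluster(c)
    if mode == "literal":
        return float(p.probs[members, k].mean())
    if mode != "walktrap":
        raise TsclustError(f"unknown mode {mode!r}")
    mean_profile = p.probs[members].mean(axis=0)
    diff = mean_profile - p.probs[k]
    return float(np.sqrt(np.sum(diff * diff / p.degrees)))


def cluster_cluster_distance(ci, cj, p: WalkProfile) -> float:
    """Degree-weighted L2 distance between two clusters' literal d_C. vectors.

    For singleton clusters this reduces exactly to the random-walk distance
    between the two cells.
    """
    ci = _check_cluster(ci)
    cj = _check_cluster(cj)
    if np.intersect1d(ci, cj).size and not np.array_equal(np.sort(ci), np.sort(cj)):
        raise TsclustError("overlapping clusters")
    di = p.probs[ci].mean(axis=0)
    dj = p.probs[cj].mean(axis=0)
    return float(np.sqrt(np.sum((di - dj) ** 2 / p.degrees)))


def _cluster_self_cost(members: np.ndarray, p: WalkProfile, mode: str) -> float:
    """sum_{k in C} d_Ck^2 for one cluster."""
    if mode == "literal":
        d = p.probs[np.ix_(members, members)].mean(axis=0)
        return float(np.sum(d * d))
    mean_profile = p.probs[members].mean(axis=0)
    diff = mean_profile[None, :] - p.probs[members]
    return float(np.sum(diff * diff / p.degrees[None, :]))


def merge_cost(ci, cj, p: WalkProfile, mode: str = "walktrap") -> float:
    """delta_sigma(Ci, Cj): change in average intra-cluster squared distance.

    Evaluated directly from the definition (self-cost of the union minus
    the parts); the agglomeration fast path uses the algebraically equal
    Ward closed form in walktrap mode.
    """
    ci = _check_cluster(ci)
    cj = _check_cluster(cj)
    if np.intersect1d(ci, cj).size:
        raise TsclustError("cannot merge overlapping clusters")
    cu = np.concatenate([ci, cj])
    n = p.n
    return (_cluster_self_cost(cu, p, mode)
            - _cluster_self_cost(ci, p, mode)
            - _cluster_self_cost(cj, p, mode)) / n


def partition_sigma(clusters, p: WalkProfile, mode: str = "walktrap") -> float:
    """sigma of an explicit partition: (1/n) sum_C sum_{k in C} d_Ck^2."""
    return sum(_cluster_self_cost(_check_cluster(c), p, mode) for c in clusters) / p.n


def _initial_pair_costs(p: WalkProfile, mode: str) -> np.ndarray:
    """delta_sigma for every singleton pair, vectorised."""
    n = p.n
    if mode == "walktrap":
        scaled = p.probs / np.sqrt(p.degrees)[None, :]
        d2 = squareform(pdist(scaled, metric="sqeuclidean"))
        return d2 / (2.0 * n)
    pd_ = np.diag(p.probs)
    u1 = (pd_[:, None] + p.probs.T) / 2.0  # d_{Cu,i} for Cu = {i, j}
    u2 = (p.probs + pd_[None, :]) / 2.0    # d_{Cu,j}
    s_u = u1 * u1 + u2 * u2
    return (s_u - (pd_**2)[:, None] - (pd_**2)[None, :]) / n


def agglomerate(p: WalkProfile, mode: str = "walktrap") -> ClusterState:
    """Full agglomeration from singletons to a single cluster.

    Ties in the merge cost are broken on the lexicographically smallest
    (cluster_a, cluster_b) id pair, ids being smallest member indices, so
    the result is deterministic and permutation-equivariant away from ties.
    """
    if mode not in MODES:
        raise TsclustError(f"unknown mode {mode!r}")
    n = p.n
    if n < 2:
        raise TsclustError("need at least 2 core cells to cluster")

    members: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    self_cost = {i: _cluster_self_cost(members[i], p, mode) for i in range(n)}
    means = {i: p.probs[i].copy() for i in range(n)} if mode == "walktrap" else None
    version = {i: 0 for i in range(n)}
    inv_deg = 1.0 / p.degrees

    cost0 = _initial_pair_costs(p, mode)
    heap: list[tuple[float, int, int, int, int]] = [
        (cost0[i, j], i, j, 0, 0) for i in range(n) for j in range(i + 1, n)
    ]
    heapq.heapify(heap)

    sigma = np.full(n + 1, np.nan)
    sigma[n] = sum(self_cost.values()) / n
    trace: list[tuple[int, int, float]] = []

    for k in range(n, 1, -1):
        while True:
            cost, a, b, va, vb = heapq.heappop(heap)
            if version.get(a) == va and version.get(b) == vb:
                break
        u = min(a, b)
        other = max(a, b)
        cu = np.concatenate([members[a], members[b]])
        if mode == "walktrap":
            mean_u = (sizes[a] * means[a] + sizes[b] * means[b]) / (sizes[a] + sizes[b])
            means[u] = mean_u
            means.pop(other, None)
            s_u = self_cost[a] + self_cost[b] + n * cost
        else:
            s_u = _cluster_self_cost(cu, p, mode)
        members[u] = cu
        sizes[u] = sizes[a] + sizes[b]
        self_cost[u] = s_u
        for d in (members, sizes, self_cost):
            d.pop(other, None)
        del version[other]
        version[u] += 1

        trace.append((u, other, float(cost)))
        sigma[k - 1] = sigma[k] + cost

        alive = [c for c in members if c != u]
        if alive:
            if mode == "walktrap":
                other_means = np.stack([means[c] for c in alive])
                diff = other_means - mean_u[None, :]
                d2 = np.sum(diff * diff * inv_deg[None, :], axis=1)
                other_sizes = np.array([sizes[c] for c in alive], dtype=float)
                costs = (sizes[u] * other_sizes / (sizes[u] + other_sizes)) * d2 / n
                for c, new_cost in zip(alive, costs):
                    lo, hi = min(u, c), max(u, c)
                    heapq.heappush(heap, (float(new_cost), lo, hi, version[lo], version[hi]))
            else:
                for c in alive:
                    both = np.concatenate([cu, members[c]])
                    new_cost = (_cluster_self_cost(both, p, mode)
                                - s_u - self_cost[c]) / n
                    lo, hi = min(u, c), max(u, c)
                    heapq.heappush(heap, (float(new_cost), lo, hi, version[lo], version[hi]))

    state = ClusterState(n=n, mode=mode, merge_trace=trace, sigma_history=sigma)
    state.partition = state.partition_at(1)
    return state


def select_k(state: ClusterState, k_min: int = DEFAULT_K_MIN,
             k_max: int | None = None) -> int:
    """Choose the number of clusters by the maximal merge-cost jump ratio.

    Scans K in [k_min, k_max] (k_max defaults to min(50, n-1)) and returns
    the K maximising eta_K = (sigma_{K-1} - sigma_K)/(sigma_K - sigma_{K+1});
    levels with a zero denominator (a cost plateau) are skipped with a
    warning, and if every level is degenerate the result falls back to
    ``k_min``.  Ties go to the smallest K.
    """
    n = state.n
    if k_max is None:
        k_max = min(DEFAULT_K_MAX_CAP, n - 1)
    k_max = min(k_max, n - 1)
    k_min = max(k_min, 2)
    if k_min > k_max:
        raise TsclustError(f"empty K range [{k_min}, {k_max}]")
    sigma = state.sigma_history
    best_k, best_eta = None, -np.inf
    skipped = []
    for k in range(k_min, k_max + 1):
        denom = sigma[k] - sigma[k + 1]
        if denom == 0:
            skipped.append(k)
            continue
        eta = (sigma[k - 1] - sigma[k]) / denom
        if eta > best_eta:
            best_k, best_eta = k, eta
    if skipped:
        warnings.warn(f"merge-cost plateau: skipped K in {skipped}", stacklevel=2)
    if best_k is None:
        warnings.warn("all levels degenerate; falling back to k_min", stacklevel=2)
        return k_min
    return best_k
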