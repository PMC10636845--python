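"""Synthetic scRNA-seq-like fixtures with planted cluster structure.

The generator emulates the features of real expression matrices that the
pipeline reacts to, at desk scale: nonnegative values, planted cell
clusters separated by blocks of marker genes, optional boundary cells
drawn midway between two cluster centroids (the cells the core/non-core
split is designed to set aside), dropout zeros, and a controllable
right-skewness regime for the gene maxima:

* ``heavy_tail`` — log-normal gene means (log-mean 2, log-SD 2) with the
  top 1% additionally scaled x100, producing the strongly right-skewed
  maxima that should trigger the log transform;
* ``uniform`` — gene means uniform on [2, 6] with no tail, which should
  leave the matrix untransformed.

Within-cluster noise is unit-SD Gaussian (truncated at zero), so
``separation`` is the marker-gene shift in within-cluster SD units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionMatrix, TsclustError


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic expression matrix.

    Attributes
    ----------
    n_cells, n_genes, k_true : int
        Matrix shape and number of planted clusters.
    separation : float
        Marker-gene mean shift between clusters, in within-cluster SD units.
    boundary_fraction : float
        Fraction of cells drawn between their own centroid and another
        cluster's (mixing weight uniform in [0.5, 0.7] toward the source,
        whose label they keep) with ``boundary_noise_factor`` x noisier
        profiles — cells near cluster boundaries with weak similarity to
        everything, the kind the core/non-core split is meant to set aside.
    skew_mode : {"heavy_tail", "uniform"}
        Right-skewness regime of the gene means (see module doc).
    dropout_rate : float in [0, 1)
        Probability that any entry is zeroed (capture failure).
    seed : int
        Seed of the single reproducible RNG stream.
    """

    n_cells: int = 300
    n_genes: int = 200
    k_true: int = 3
    separation: float = 6.0
    boundary_fraction: float = 0.0
    skew_mode: str = "uniform"
    dropout_rate: float = 0.1
    seed: int = 0

    markers_per_cluster: int = 20
    noise_sd: float = 1.0
    boundary_noise_factor: float = 3.0


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Draw one matrix + planted labels; byte-identical for equal specs."""
    if spec.k_true > spec.n_cells:
        raise TsclustError("k_true cannot exceed n_cells")
    if spec.k_true < 1:
        raise TsclustError("k_true must be positive")
    if spec.skew_mode not in ("heavy_tail", "uniform"):
        raise TsclustError(f"unknown skew_mode {spec.skew_mode!r}")
    if not 0.0 <= spec.dropout_rate < 1.0:
        raise TsclustError("dropout_rate must be in [0, 1)")
    rng = np.random.default_rng(spec.seed)
    n, p, k = spec.n_cells, spec.n_genes, spec.k_true

    if spec.skew_mode == "heavy_tail":
        base = rng.lognormal(mean=2.0, sigma=2.0, size=p)
        n_top = max(1, p // 100)
        top = np.argsort(base)[-n_top:]
        base[top] *= 100.0
    else:
        base = rng.uniform(2.0, 6.0, size=p)

    block = min(spec.markers_per_cluster, p // k) or 1
    centroids = np.tile(base, (k, 1))
    for c in range(k):
        centroids[c, c * block:(c + 1) * block] += spec.separation * spec.noise_sd

    labels = rng.permutation(np.arange(n) % k)
    values = rng.normal(loc=centroids[labels], scale=spec.noise_sd, size=(n, p))

    n_boundary = int(round(spec.boundary_fraction * n))
    if n_boundary:
        which = rng.choice(n, size=n_boundary, replace=False)
        partner = (labels[which] + rng.integers(1, k, size=n_boundary)) % k
        # spread along the connecting line, leaning toward the source
        # centroid, so boundary cells are diffuse (no phantom midpoint
        # cluster) and their planted label remains the nearest center;
        # the inflated noise keeps their similarities to everything weak
        alpha = rng.uniform(0.5, 0.7, size=n_boundary)[:, None]
        mid = alpha * centroids[labels[which]] + (1 - alpha) * centroids[partner]
        values[which] = rng.normal(
            loc=mid, scale=spec.boundary_noise_factor * spec.noise_sd)

    # mask drawn unconditionally so streams with different rates stay aligned
    mask = rng.random((n, p)) < spec.dropout_rate
    values = np.clip(values, 0.0, None)
    values[mask] = 0.0

    x = ExpressionMatrix(values=values)
    return x, labels
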