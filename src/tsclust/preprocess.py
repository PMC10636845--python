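"""Gene filtering and the right-skewness-gated log transformation.

scRNA-seq expression is often strongly right-skewed: a handful of genes
reach very large values and dominate any distance between cells.  The
right-skewed coefficient (RSC) quantifies this on the per-gene maxima

    RSC = sum_{g_i_max >= mu} (g_i_max - mu) / (l * mu)

where ``mu`` is the mean of the gene maxima, and ``l`` counts maxima at or
above ``mu``; gene maxima outside the Tukey fence [Q1 - 1.5 IQR, Q3 + 1.5 IQR]
are excluded first so single extreme genes do not decide the transform.
When RSC exceeds a threshold (default 0.8) the matrix is log2(x+1)
transformed; otherwise it is left on its original scale — log-transforming
data that are not right-skewed distorts the differences between genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import ExpressionMatrix, TsclustError

DEFAULT_MIN_EXPRESSED_FRACTION = 0.02
DEFAULT_RSC_THRESHOLD = 0.8


@dataclass
class RSCReport:
    """Outcome of the right-skewness measurement.

    Attributes
    ----------
    rsc : float
        The right-skewed coefficient (nonnegative).
    mu : float
        Mean of the retained gene maxima.
    l : int
        Number of retained gene maxima >= mu.
    n_outlier_genes_removed : int
        Genes excluded by the Tukey IQR fence (for RSC only; they stay in
        the matrix handed downstream).
    q1, q3 : float
        First/third quartile of the gene maxima (linear-interpolation
        quartiles; see ``quartile_method``).
    log_applied : bool
        Whether the log transform was applied.
    quartile_method : str
        Quartile convention used, recorded so alternates can be compared.
    """

    rsc: float
    mu: float
    l: int
    n_outlier_genes_removed: int
    q1: float
    q3: float
    log_applied: bool = False
    quartile_method: str = "linear"


def filter_low_expressed_genes(
    x: ExpressionMatrix, min_fraction: float = DEFAULT_MIN_EXPRESSED_FRACTION
) -> ExpressionMatrix:
    """Drop genes expressed (value > 0) in less than ``min_fraction`` of cells.

    Genes at exactly the threshold are kept (removal is strictly "less
    than").  Cell set and gene order are preserved.
    """
    if x.log_transformed:
        raise TsclustError("gene filter expects a non-log-transformed matrix")
    if not 0.0 <= min_fraction <= 1.0:
        raise TsclustError("min_fraction must be in [0, 1]")
    if x.n_cells == 0 or x.n_genes == 0:
        raise TsclustError("empty input")
    frac_expressed = (x.values > 0).mean(axis=0)
    keep = frac_expressed >= min_fraction
    if not keep.any():
        raise TsclustError("no genes survive filter")
    return x.subset_genes(keep)


def compute_rsc(x: ExpressionMatrix) -> RSCReport:
    """Measure the right-skewness of the gene-maxima distribution.

    Raises on degenerate input: fewer than two genes survive the IQR
    fence, or the retained maxima average to zero (all-zero matrix).
    """
    if x.n_genes < 2:
        raise TsclustError("RSC needs at least 2 genes")
    gmax = x.values.max(axis=0)
    q1, q3 = np.percentile(gmax, [25, 75])  # linear interpolation ("type 7")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    retained = gmax[(gmax >= lo) & (gmax <= hi)]
    n_removed = gmax.size - retained.size
    if retained.size < 2:
        raise TsclustError("fewer than 2 genes retained for RSC")
    mu = float(retained.mean())
    if mu == 0.0:
        raise TsclustError("degenerate matrix, RSC undefined")
    upper = retained[retained >= mu]
    l = int(upper.size)
    # fp rounding can push the mean one ulp above identical maxima -> l = 0;
    # no mass at or above the mean means no right skew
    rsc = float((upper - mu).sum() / (l * mu)) if l else 0.0
    return RSCReport(rsc=rsc, mu=mu, l=l, n_outlier_genes_removed=n_removed,
                     q1=float(q1), q3=float(q3))


def maybe_log_transform(
    x: ExpressionMatrix,
    rsc_threshold: float = DEFAULT_RSC_THRESHOLD,
    force: str = "auto",
) -> tuple[ExpressionMatrix, RSCReport]:
    """Apply log2(x+1) iff RSC exceeds ``rsc_threshold`` (or ``force="on"``).

    ``force`` is tri-state: ``"auto"`` follows the RSC decision, ``"on"``
    and ``"off"`` override it (RSC is still computed and reported).
    """
    if x.log_transformed:
        raise TsclustError("matrix is already log-transformed")
    if force not in ("auto", "on", "off"):
        raise TsclustError(f"force must be auto/on/off, got {force!r}")
    report = compute_rsc(x)
    apply_log = report.rsc > rsc_threshold if force == "auto" else force == "on"
    report.log_applied = apply_log
    if not apply_log:
        return x, report
    out = x.copy()
    out.values = np.log2(out.values + 1.0)
    out.log_transformed = True
    return out, report


def preprocess(
    x: ExpressionMatrix,
    min_expressed_fraction: float = DEFAULT_MIN_EXPRESSED_FRACTION,
    rsc_threshold: float = DEFAULT_RSC_THRESHOLD,
    force_log: str = "auto",
) -> tuple[ExpressionMatrix, RSCReport]:
    """Full preprocessing: gene filter, then RSC-gated log transform."""
    filtered = filter_low_expressed_genes(x, min_expressed_fraction)
    if filtered.n_genes < x.n_genes:
        warnings.warn(
            f"removed {x.n_genes - filtered.n_genes} genes expressed in fewer "
            f"than {min_expressed_fraction:.0%} of cells", stacklevel=2)
    return maybe_log_transform(filtered, rsc_threshold, force_log)
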