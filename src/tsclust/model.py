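"""Two-step clustering model and results objects.

``TSC`` bundles the full pipeline — preprocessing, similarity-graph
construction, core-cell selection, random-walk distances, Ward-style
agglomeration with automatic cluster-number choice, and nearest-center
assignment of the remaining cells — behind a statsmodels-like interface::

    model = TSC(matrix, metric="pcc", edge_fraction=0.25)
    res = model.fit()
    print(res.summary())
    res.score(true_labels)            # ARI / NMI / AMI / Acc
    res.to_frame()                    # per-cell labels + core flags

The one-step ablation (``one_step=True``) forces ``edge_fraction = 1`` so
every cell with any positive similarity is clustered directly, without the
core/non-core split.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import assign as assign_mod
from . import graph as graph_mod
from . import hierarchy, metrics, preprocess, walk
from .data import ExpressionMatrix, TsclustError, write_labels, write_metadata

logger = logging.getLogger("tsclust")


class TSC:
    """Two-step clustering of a cells x genes expression matrix.

    Parameters
    ----------
    data : ExpressionMatrix, DataFrame (cells x genes) or ndarray
        Nonnegative expression values.
    metric : {"ed", "md", "pcc", "scc", "snn"}
        Cell-similarity metric for the graph (default Pearson correlation,
        the best performer among the five).
    edge_fraction : float in (0, 1]
        Fraction of the strongest edges that defines the core cells
        (default 0.25).
    walk_steps : int
        Random-walk length t (default 4).
    snn_k : int
        Neighbourhood size for the SNN metric.
    min_expressed_fraction, rsc_threshold, force_log
        Preprocessing controls (gene filter, RSC gate for log2(x+1)).
    k_min, k_max, fixed_k
        Cluster-number search range, or a fixed K bypassing the search.
    one_step : bool
        Ablation mode: cluster all cells directly (edge_fraction = 1).
    linkage : {"walktrap", "literal"}
        Reading of the cell-to-cluster distance in the merge criterion.
    assign_metric : {"euclidean", "pcc"}
        Distance used for the non-core nearest-center assignment.
    """

    def __init__(
        self,
        data,
        cell_ids=None,
        gene_ids=None,
        *,
        metric: str = "pcc",
        edge_fraction: float = graph_mod.DEFAULT_EDGE_FRACTION,
        walk_steps: int = walk.DEFAULT_WALK_STEPS,
        snn_k: int = graph_mod.DEFAULT_SNN_K,
        min_expressed_fraction: float = preprocess.DEFAULT_MIN_EXPRESSED_FRACTION,
        rsc_threshold: float = preprocess.DEFAULT_RSC_THRESHOLD,
        force_log: str = "auto",
        k_min: int = hierarchy.DEFAULT_K_MIN,
        k_max: int | None = None,
        fixed_k: int | None = None,
        one_step: bool = False,
        linkage: str = "walktrap",
        assign_metric: str = "euclidean",
    ) -> None:
        if isinstance(data, ExpressionMatrix):
            self.data = data
        elif isinstance(data, pd.DataFrame):
            self.data = ExpressionMatrix.from_dataframe(data, orientation="cells_by_genes")
        else:
            self.data = ExpressionMatrix(np.asarray(data, dtype=float),
                                         cell_ids=cell_ids, gene_ids=gene_ids)
        self.metric = metric
        self.edge_fraction = 1.0 if one_step else edge_fraction
        self.walk_steps = walk_steps
        self.snn_k = snn_k
        self.min_expressed_fraction = min_expressed_fraction
        self.rsc_threshold = rsc_threshold
        self.force_log = force_log
        self.k_min = k_min
        self.k_max = k_max
        self.fixed_k = fixed_k
        self.one_step = one_step
        self.linkage = linkage
        self.assign_metric = assign_metric

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, orientation: str = "genes_by_cells",
                       **kwargs) -> "TSC":
        """Build from a labelled table; ``orientation`` names the rows."""
        return cls(ExpressionMatrix.from_dataframe(df, orientation=orientation),
                   **kwargs)

    def config(self) -> dict[str, Any]:
        return {
            "metric": self.metric,
            "edge_fraction": self.edge_fraction,
            "walk_steps": self.walk_steps,
            "snn_k": self.snn_k,
            "min_expressed_fraction": self.min_expressed_fraction,
            "rsc_threshold": self.rsc_threshold,
            "force_log": self.force_log,
            "k_min": self.k_min,
            "k_max": self.k_max,
            "fixed_k": self.fixed_k,
            "one_step": self.one_step,
            "linkage": self.linkage,
            "assign_metric": self.assign_metric,
        }

    def fit(self) -> "TSCResults":
        """Run the full two-step pipeline and return the results object."""
        timings: dict[str, float] = {}

        def stage(name):
            timings[name] = time.perf_counter()
            return name

        def done(name):
            timings[name] = time.perf_counter() - timings[name]

        try:
            stage("preprocess")
            x_pre, rsc_report = preprocess.preprocess(
                self.data, self.min_expressed_fraction,
                self.rsc_threshold, self.force_log)
            done("preprocess")
            logger.info("RSC = %.3f (log %s)", rsc_report.rsc,
                        "applied" if rsc_report.log_applied else "not applied")

            stage("graph")
            g = graph_mod.pairwise_similarity(x_pre, self.metric, self.snn_k)
            g_cc, split = graph_mod.select_core_cells(g, self.edge_fraction)
            done("graph")
            logger.info("core cells: %d / %d", len(split.core_cell_ids), x_pre.n_cells)
            if len(split.core_cell_ids) < 2:
                raise TsclustError("fewer than 2 core cells; lower edge_fraction?")

            stage("walk")
            profile = walk.walk_profile(g_cc, self.walk_steps)
            done("walk")

            stage("agglomerate")
            state = hierarchy.agglomerate(profile, mode=self.linkage)
            if self.fixed_k is not None:
                k = self.fixed_k
                if not 1 <= k <= state.n:
                    raise TsclustError(f"fixed_k={k} outside [1, {state.n}]")
            else:
                k = hierarchy.select_k(state, self.k_min, self.k_max)
            core_labels = state.labels_at(k)
            state.partition = {i: int(lab) for i, lab in enumerate(core_labels)}
            done("agglomerate")
            logger.info("selected K = %d", k)

            stage("assign")
            centers = assign_mod.compute_centers(x_pre, split.core_index, core_labels)
            result = assign_mod.assign_noncore(
                x_pre, centers, split.core_index, core_labels,
                split.noncore_index, metric=self.assign_metric)
            done("assign")
        except TsclustError:
            raise
        for name, dt in timings.items():
            logger.info("stage %-12s %.3f s", name, dt)
        return TSCResults(model=self, result=result, rsc_report=rsc_report,
                          core_split=split, cluster_state=state,
                          preprocessed=x_pre, walk=profile, timings=timings)


@dataclass
class TSCResults:
    """Fitted two-step clustering: labels, diagnostics and exports."""

    model: TSC
    result: assign_mod.TSCResult
    rsc_report: preprocess.RSCReport
    core_split: graph_mod.CoreSplit
    cluster_state: hierarchy.ClusterState
    preprocessed: ExpressionMatrix
    walk: walk.WalkProfile
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        return self.result.labels

    @property
    def k(self) -> int:
        return self.result.k

    @property
    def is_core(self) -> np.ndarray:
        return self.result.is_core

    @property
    def centers(self) -> pd.DataFrame:
        return pd.DataFrame(self.result.centers,
                            index=[f"cluster_{i}" for i in range(1, self.k + 1)],
                            columns=self.preprocessed.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.result.cell_ids,
            "cluster": self.labels,
            "is_core": self.is_core,
        })

    def score(self, labels_true) -> dict[str, float]:
        """ARI/NMI/AMI/Acc against ground truth, plus core-cell-only ARI."""
        labels_true = np.asarray(labels_true)
        scores = metrics.clustering_scores(labels_true, self.labels)
        if self.is_core.any():
            scores["ari_core"] = metrics.adjusted_rand_index(
                labels_true[self.is_core], self.labels[self.is_core])
        return scores

    def summary(self) -> str:
        cfg = self.model.config()
        sizes = np.bincount(self.labels, minlength=self.k + 1)[1:]
        lines = [
            "Two-step clustering results",
            "=" * 42,
            f"cells                 {len(self.labels):>8d}",
            f"genes (after filter)  {self.preprocessed.n_genes:>8d}",
            f"similarity metric     {cfg['metric']:>8s}",
            f"edge fraction         {cfg['edge_fraction']:>8.2f}",
            f"walk steps t          {cfg['walk_steps']:>8d}",
            f"RSC                   {self.rsc_report.rsc:>8.3f}",
            f"log2(x+1) applied     {str(self.rsc_report.log_applied):>8s}",
            f"core cells            {int(self.is_core.sum()):>8d}",
            f"non-core cells        {int((~self.is_core).sum()):>8d}",
            f"clusters K            {self.k:>8d}"
            + ("  (fixed)" if cfg["fixed_k"] is not None else "  (auto)"),
            "-" * 42,
            "cluster sizes         " + " ".join(str(s) for s in sizes),
        ]
        return "\n".join(lines)

    def save(self, outdir: str | Path, prefix: str = "tsc") -> dict[str, Path]:
        """Write labels TSV, centers TSV and run-metadata JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "labels": outdir / f"{prefix}_labels.tsv",
            "centers": outdir / f"{prefix}_centers.tsv",
            "metadata": outdir / f"{prefix}_metadata.json",
        }
        write_labels(paths["labels"], self.result.cell_ids, self.labels, self.is_core)
        self.centers.to_csv(paths["centers"], sep="\t")
        meta = dict(self.model.config())
        meta.update({
            "rsc": self.rsc_report.rsc,
            "log_applied": self.rsc_report.log_applied,
            "n_core_cells": int(self.is_core.sum()),
            "chosen_k": self.k,
            "s_c": self.core_split.s_c,
            "timings_s": {k: round(v, 4) for k, v in self.timings.items()},
        })
        write_metadata(paths["metadata"], meta)
        return paths

    def plot_merge_costs(self, ax=None, k_max: int = 30):
        """Plot sigma_K against K — the curve the K-selection ratio reads."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ks = np.arange(1, min(k_max, self.cluster_state.n) + 1)
        ax.plot(ks, self.cluster_state.sigma_history[ks], marker="o", ms=3)
        ax.axvline(self.k, color="red", ls="--", label=f"chosen K = {self.k}")
        ax.set_xlabel("number of clusters K")
        ax.set_ylabel(r"average intra-cluster squared distance $\sigma_K$")
        ax.legend()
        return ax
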