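"""Expression-matrix container and plain-text readers/writers.

The package's primary input is a cells x genes matrix of nonnegative
expression values (UMI counts, CPM, FPKM ...).  Dense tables are read with
pandas; sparse matrices use the MatrixMarket triplet format with sidecar
row/column label files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class TsclustError(ValueError):
    """Base class for input/contract violations raised by this package."""


@dataclass
class ExpressionMatrix:
    """Cells x genes nonnegative expression matrix with identifiers.

    Parameters
    ----------
    values : ndarray, shape (n_cells, n_genes)
        Nonnegative expression values (before any log transformation).
    cell_ids, gene_ids : sequences of unique strings
        Row and column identifiers.
    log_transformed : bool
        Whether ``values`` already hold ``log2(x + 1)`` expression.
    """

    values: np.ndarray
    cell_ids: list[str] = field(default=None)  # type: ignore[assignment]
    gene_ids: list[str] = field(default=None)  # type: ignore[assignment]
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise TsclustError("expression values must be a 2-D matrix")
        m, p = self.values.shape
        if self.cell_ids is None:
            self.cell_ids = [f"cell_{i}" for i in range(m)]
        if self.gene_ids is None:
            self.gene_ids = [f"gene_{j}" for j in range(p)]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.cell_ids) != m or len(self.gene_ids) != p:
            raise TsclustError("id lengths do not match matrix shape")
        if len(set(self.cell_ids)) != m:
            raise TsclustError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != p:
            raise TsclustError("duplicate gene identifiers")
        if not self.log_transformed and np.any(self.values < 0):
            raise TsclustError("expression values must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, orientation: str = "genes_by_cells"
    ) -> "ExpressionMatrix":
        """Build from a labelled DataFrame.

        ``orientation`` says what the *rows* of ``df`` are: the conventional
        expression-table layout puts genes in rows (``genes_by_cells``);
        ``cells_by_genes`` means rows are cells.
        """
        if orientation not in ("genes_by_cells", "cells_by_genes"):
            raise TsclustError(f"unknown orientation {orientation!r}")
        if orientation == "genes_by_cells":
            df = df.T
        return cls(
            values=df.to_numpy(dtype=float),
            cell_ids=list(df.index.astype(str)),
            gene_ids=list(df.columns.astype(str)),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Return a copy restricted to the genes selected by boolean/index mask."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            values=self.values[:, keep].copy(),
            gene_ids=[self.gene_ids[j] for j in keep],
        )

    def copy(self) -> "ExpressionMatrix":
        return replace(self, values=self.values.copy(),
                       cell_ids=list(self.cell_ids), gene_ids=list(self.gene_ids))


def read_expression(
    path: str | Path,
    *,
    fmt: str | None = None,
    orientation: str = "genes_by_cells",
    row_labels: str | Path | None = None,
    col_labels: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    ``fmt`` is inferred from the suffix when not given: ``.mtx`` is
    MatrixMarket (with sidecar ``<stem>.rows`` / ``<stem>.cols`` label files,
    one label per line, unless ``row_labels``/``col_labels`` point elsewhere);
    anything else is a dense delimited table with labels in the first row and
    column (comma- or tab-separated, sniffed by pandas).
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix.lower() == ".mtx" else "dense"
    if fmt == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        row_labels = Path(row_labels) if row_labels else path.with_suffix(".rows")
        col_labels = Path(col_labels) if col_labels else path.with_suffix(".cols")
        rows = row_labels.read_text().split()
        cols = col_labels.read_text().split()
        df = pd.DataFrame(np.asarray(mat, dtype=float), index=rows, columns=cols)
    else:
        df = pd.read_csv(path, index_col=0, sep=None, engine="python")
    return ExpressionMatrix.from_dataframe(df, orientation=orientation)


def write_expression(x: ExpressionMatrix, path: str | Path,
                     orientation: str = "genes_by_cells") -> None:
    df = x.to_dataframe()
    if orientation == "genes_by_cells":
        df = df.T
    df.to_csv(path, sep="\t")


def read_labels(path: str | Path) -> np.ndarray:
    """Read cluster labels: one per line, or a TSV with a cluster/label column."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    col = -1
    for name in ("cluster", "label"):
        if name in header:
            col = header.index(name)
            lines = lines[1:]
            break
    return np.array([ln.split("\t")[col] for ln in lines])


def write_labels(path: str | Path, cell_ids: Sequence[str], labels: np.ndarray,
                 is_core: np.ndarray | None = None) -> None:
    with open(path, "w") as fh:
        if is_core is None:
            fh.write("cell_id\tcluster\n")
            for cid, lab in zip(cell_ids, labels):
                fh.write(f"{cid}\t{lab}\n")
        else:
            fh.write("cell_id\tcluster\tis_core\n")
            for cid, lab, core in zip(cell_ids, labels, is_core):
                fh.write(f"{cid}\t{lab}\t{int(core)}\n")


def write_metadata(path: str | Path, meta: dict) -> None:
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, default=float)
        fh.write("\n")
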