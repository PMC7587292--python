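"""Core in-memory containers and file round-trips.

Expression data is held cells-by-genes (N x D): row ``n`` is the expression
profile of cell ``n`` across ``D`` features.  Embeddings are N x d coordinate
matrices.  Dense matrices round-trip through CSV/TSV (header row of gene ids,
first column of cell ids); sparse matrices through MatrixMarket MTX with
``genes.tsv``/``barcodes.tsv`` sidecars in the 10x convention (genes in rows,
cells in columns — transposed on read).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """A file does not conform to its documented on-disk layout."""


@dataclass
class ExpressionMatrix:
    """N cells x D features with optional names and per-cell labels.

    Invariants: all values finite, N >= 2, D >= 1, cell and gene identifiers
    unique, labels (when present) of length N.
    """

    values: np.ndarray
    cell_ids: Optional[Sequence[str]] = None
    gene_ids: Optional[Sequence[str]] = None
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, d = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 cells, got {n}")
        if d < 1:
            raise ValueError("need at least 1 feature")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain non-finite entries")
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i}" for i in range(n)]
        if self.gene_ids is None:
            self.gene_ids = [f"gene{j}" for j in range(d)]
        self.cell_ids = list(map(str, self.cell_ids))
        self.gene_ids = list(map(str, self.gene_ids))
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length does not match row count")
        if len(self.gene_ids) != d:
            raise ValueError("gene_ids length does not match column count")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids are not unique")
        if len(set(self.gene_ids)) != d:
            raise ValueError("gene_ids are not unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels length does not match cell count")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.values[idx],
            [self.cell_ids[i] for i in idx],
            list(self.gene_ids),
            None if self.labels is None else self.labels[idx],
        )


@dataclass
class Embedding:
    """N x d low-dimensional coordinates of the cells."""

    coords: np.ndarray
    cell_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2:
            raise ValueError("embedding coordinates must be a 2-D matrix")
        if self.coords.shape[1] < 1:
            raise ValueError("embedding dimension must be >= 1")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite coordinates")
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i}" for i in range(self.coords.shape[0])]
        self.cell_ids = list(map(str, self.cell_ids))
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValueError("cell_ids length does not match row count")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# readers / writers


def read_dense(
    path: str | Path,
    sep: Optional[str] = None,
    genes_in_rows: bool = False,
    labels_path: Optional[str | Path] = None,
) -> ExpressionMatrix:
    """Read a dense CSV/TSV matrix (cells in rows unless ``genes_in_rows``).

    Layout: header row of gene ids, first column of cell ids.  ``sep`` is
    inferred from the suffix (``.tsv``/``.txt`` -> tab) when not given.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if genes_in_rows:
        df = df.T
    labels = _read_labels(labels_path, df.shape[0]) if labels_path else None
    return ExpressionMatrix(
        df.to_numpy(dtype=np.float64),
        cell_ids=df.index.astype(str).tolist(),
        gene_ids=df.columns.astype(str).tolist(),
        labels=labels,
    )


def write_dense(m: ExpressionMatrix, path: str | Path, sep: Optional[str] = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    pd.DataFrame(m.values, index=m.cell_ids, columns=m.gene_ids).to_csv(path, sep=sep)


def read_mtx(
    mtx_path: str | Path,
    genes_path: Optional[str | Path] = None,
    barcodes_path: Optional[str | Path] = None,
    labels_path: Optional[str | Path] = None,
) -> ExpressionMatrix:
    """Read a MatrixMarket matrix with 10x-style sidecars.

    The MTX stores genes x cells; sidecars default to ``genes.tsv`` and
    ``barcodes.tsv`` next to the matrix file.
    """
    mtx_path = Path(mtx_path)
    mat = scipy.io.mmread(mtx_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    values = np.asarray(mat, dtype=np.float64).T  # -> cells x genes
    genes_path = Path(genes_path) if genes_path else mtx_path.with_name("genes.tsv")
    barcodes_path = (
        Path(barcodes_path) if barcodes_path else mtx_path.with_name("barcodes.tsv")
    )
    gene_ids = cell_ids = None
    if genes_path.exists():
        gdf = pd.read_csv(genes_path, sep="\t", header=None)
        if len(gdf) != values.shape[1]:
            raise FormatError(
                f"genes sidecar has {len(gdf)} rows, matrix has {values.shape[1]} genes"
            )
        gene_ids = gdf.iloc[:, 0].astype(str).tolist()
    if barcodes_path.exists():
        bdf = pd.read_csv(barcodes_path, sep="\t", header=None)
        if len(bdf) != values.shape[0]:
            raise FormatError(
                f"barcodes sidecar has {len(bdf)} rows, matrix has {values.shape[0]} cells"
            )
        cell_ids = bdf.iloc[:, 0].astype(str).tolist()
    labels = _read_labels(labels_path, values.shape[0]) if labels_path else None
    return ExpressionMatrix(values, cell_ids, gene_ids, labels)


def write_mtx(m: ExpressionMatrix, mtx_path: str | Path) -> None:
    """Write genes x cells MTX plus genes.tsv / barcodes.tsv sidecars."""
    mtx_path = Path(mtx_path)
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.csr_matrix(m.values.T))
    pd.Series(m.gene_ids).to_csv(mtx_path.with_name("genes.tsv"), sep="\t",
                                 header=False, index=False)
    pd.Series(m.cell_ids).to_csv(mtx_path.with_name("barcodes.tsv"), sep="\t",
                                 header=False, index=False)


def _read_labels(path: str | Path, n: int) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None)
    col = df.iloc[:, -1] if df.shape[1] > 1 else df.iloc[:, 0]
    labels = col.to_numpy()
    if len(labels) != n:
        raise FormatError(f"labels file has {len(labels)} rows, expected {n}")
    return labels


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    pd.Series(labels).to_csv(path, sep="\t", header=False, index=False)


def write_embedding(e: Embedding, path: str | Path) -> None:
    """Write an embedding as CSV ``cell_id,x1..xd``, one row per cell."""
    cols = [f"x{i + 1}" for i in range(e.d)]
    df = pd.DataFrame(e.coords, columns=cols)
    df.insert(0, "cell_id", e.cell_ids)
    df.to_csv(path, index=False)


def read_embedding(path: str | Path) -> Embedding:
    df = pd.read_csv(path)
    if "cell_id" not in df.columns:
        raise FormatError("embedding CSV is missing the 'cell_id' column")
    coords = df.drop(columns=["cell_id"]).to_numpy(dtype=np.float64)
    return Embedding(coords, df["cell_id"].astype(str).tolist())
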