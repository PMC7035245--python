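"""Core in-memory containers for UMI count data.

A :class:`CountMatrix` holds raw genes x cells unique-molecular-identifier
(UMI) counts as a sparse integer matrix with gene ids and cell barcodes.
A :class:`NormMatrix` holds the library-size normalized, log-transformed
expression derived from it.  Cell-level metadata travels separately as a
pandas DataFrame indexed by barcode (one row per retained cell).
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class ValidationError(ValueError):
    """Raised when an input violates a container or operation contract."""


class FormatError(ValueError):
    """Raised when an on-disk file does not parse as the expected format."""


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids.tolist())):
        dup = pd.Index(ids)[pd.Index(ids).duplicated()].tolist()[:5]
        raise FormatError(f"duplicate {what}: {dup}")


@dataclass
class CountMatrix:
    """Genes x cells non-negative integer UMI counts.

    Parameters
    ----------
    values
        Sparse ``(n_genes, n_cells)`` matrix of non-negative integers.
    gene_ids
        Unique gene symbols/ids, one per row.
    barcodes
        Unique cell barcodes, one per column.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} barcodes"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.barcodes, "barcodes")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValidationError("negative counts are not allowed")
        if not np.issubdtype(self.values.dtype, np.integer):
            data = self.values.data
            if data.size and not np.allclose(data, np.round(data)):
                raise ValidationError("counts must be integers")
            self.values = self.values.astype(np.int64)

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, index: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.values[index], self.gene_ids[index], self.barcodes)

    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.values[:, index], self.gene_ids, self.barcodes[index])

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)

    def umi_per_cell(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()


@dataclass
class NormMatrix:
    """Log-normalized expression: ``e = ln(1 + s * x / T)`` per gene and cell.

    ``T`` is the cell's total UMI count and ``s`` the normalization scale
    (counts per 10,000 by default).  Zero counts map to zero exactly, so the
    sparsity pattern of the source :class:`CountMatrix` is preserved.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    scale: float = 10_000.0
    source_n_umi: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.values.nnz and self.values.data.min() < 0:
            raise ValidationError("normalized expression must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)

    def gene_vector(self, gene: str) -> np.ndarray:
        """Dense per-cell expression vector of one gene."""
        idx = self.gene_index().get_loc(gene)
        return np.asarray(self.values[idx].todense()).ravel()

    def dense(self, genes: list[str] | None = None) -> pd.DataFrame:
        """Dense genes x cells frame (use only on small selections)."""
        if genes is None:
            mat, ids = self.values, self.gene_ids
        else:
            pos = self.gene_index().get_indexer(genes)
            if (pos < 0).any():
                missing = [g for g, p in zip(genes, pos) if p < 0]
                raise ValidationError(f"genes not in matrix: {missing[:5]}")
            mat, ids = self.values[pos], np.asarray(genes, dtype=object)
        return pd.DataFrame(mat.toarray(), index=ids, columns=self.barcodes)


# ---------------------------------------------------------------------------
# I/O: MatrixMarket triplet + TSV sidecars, and dense TSV
# ---------------------------------------------------------------------------

def read_counts(matrix_path: str | os.PathLike,
                genes_path: str | os.PathLike,
                barcodes_path: str | os.PathLike) -> CountMatrix:
    """Read a MatrixMarket count matrix with gene/barcode TSV sidecars.

    Genes are rows. The sidecar files carry one id per line (first TSV
    column if multi-column). Round-trips bit-exactly with
    :func:`write_counts`; duplicate ids raise :class:`FormatError`.
    """
    try:
        mat = scipy.io.mmread(os.fspath(matrix_path))
    except Exception as exc:  # pragma: no cover - message passthrough
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    genes = _read_id_column(genes_path)
    barcodes = _read_id_column(barcodes_path)
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"MTX shape {mat.shape} does not match sidecars "
            f"({len(genes)} genes, {len(barcodes)} barcodes)"
        )
    return CountMatrix(mat.astype(np.int64), genes, barcodes)


def _read_id_column(path: str | os.PathLike) -> np.ndarray:
    with open(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return np.asarray(ids, dtype=object)


def write_counts(counts: CountMatrix, out_dir: str | os.PathLike,
                 prefix: str = "") -> dict[str, str]:
    """Write MTX + genes.tsv + barcodes.tsv under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "matrix": os.path.join(out_dir, f"{prefix}matrix.mtx"),
        "genes": os.path.join(out_dir, f"{prefix}genes.tsv"),
        "barcodes": os.path.join(out_dir, f"{prefix}barcodes.tsv"),
    }
    scipy.io.mmwrite(paths["matrix"], counts.values.tocoo(), field="integer")
    for key, ids in (("genes", counts.gene_ids), ("barcodes", counts.barcodes)):
        with open(paths[key], "w") as fh:
            fh.write("\n".join(map(str, ids)) + ("\n" if len(ids) else ""))
    return paths


def read_dense_tsv(path: str | os.PathLike) -> CountMatrix:
    """Read a dense genes x cells TSV (header = barcodes, first column = gene ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty and df.columns.empty:
        return CountMatrix(sp.csr_matrix((0, 0), dtype=np.int64),
                           np.array([], dtype=object), np.array([], dtype=object))
    values = df.to_numpy()
    if not np.allclose(values, np.round(values)) or values.min() < 0:
        raise FormatError("dense TSV must contain non-negative integer counts")
    return CountMatrix(sp.csr_matrix(values.astype(np.int64)),
                       df.index.to_numpy(dtype=object),
                       df.columns.to_numpy(dtype=object))


def read_cell_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read per-cell metadata TSV indexed by barcode."""
    return pd.read_csv(path, sep="\t", index_col=0)


def counts_to_tsv_string(counts: CountMatrix) -> str:
    """Dense TSV serialization (small matrices only; used in round-trip tests)."""
    buf = _io.StringIO()
    pd.DataFrame(counts.values.toarray(), index=counts.gene_ids,
                 columns=counts.barcodes).to_csv(buf, sep="\t")
    return buf.getvalue()
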