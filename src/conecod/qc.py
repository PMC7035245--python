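"""Cell and gene quality control, normalization, and variable-gene selection.

The filtering rules mirror standard droplet scRNA-seq practice for retinal
organoid data: cells must express a minimum number of genes and stay below a
mitochondrial-content ceiling (20% for late-stage / day-170-like runs, 15%
for day-100-like runs), and genes must be detected in a minimum number of
cells.  Normalization is counts-per-10,000 followed by natural log1p, the
convention behind "average natural log fold change" statistics downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, NormMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    """Cell/gene filter thresholds.

    ``max_mito_fraction`` defaults to 0.20 (late-stage organoids); use 0.15
    for day-100-like runs. Cells are retained when they express at least
    ``min_genes_per_cell`` genes AND have mitochondrial fraction at or below
    ``max_mito_fraction``. Genes are retained when detected in at least
    ``min_cells_per_gene`` cells.
    """

    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.20
    min_cells_per_gene: int = 2
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0 or self.min_cells_per_gene < 0:
            raise ValidationError("QC thresholds must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValidationError("max_mito_fraction must lie in [0, 1]")


def compute_cell_qc(counts: CountMatrix, mito_prefix: str = "MT-",
                    metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-cell QC statistics: ``n_umi``, ``n_genes``, ``mito_fraction``.

    ``mito_fraction`` is the share of a cell's UMIs on genes whose id starts
    with ``mito_prefix``; cells with zero UMIs get 0.  If ``metadata`` is
    given (indexed by barcode) its columns are carried alongside.
    """
    csc = counts.values.tocsc()
    n_umi = np.asarray(csc.sum(axis=0)).ravel().astype(np.int64)
    n_genes = np.diff(csc.indptr)
    is_mito = np.array([str(g).startswith(mito_prefix) for g in counts.gene_ids])
    if is_mito.any():
        mito_umi = np.asarray(csc[is_mito].sum(axis=0)).ravel()
    else:
        mito_umi = np.zeros(counts.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(n_umi > 0, mito_umi / np.maximum(n_umi, 1), 0.0)
    ann = pd.DataFrame(
        {"n_umi": n_umi, "n_genes": n_genes, "mito_fraction": mito_fraction},
        index=pd.Index(counts.barcodes, name="barcode"),
    )
    if metadata is not None:
        extra = metadata.reindex(ann.index)
        for col in extra.columns:
            if col not in ann.columns:
                ann[col] = extra[col]
    return ann


def filter_cells(counts: CountMatrix, annotation: pd.DataFrame,
                 qc: QCConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop cells expressing fewer than ``min_genes_per_cell`` genes or
    exceeding ``max_mito_fraction``; cell order is preserved."""
    if len(annotation) != counts.n_cells:
        raise ValidationError("annotation is not aligned to the count matrix")
    keep = ((annotation["n_genes"].to_numpy() >= qc.min_genes_per_cell)
            & (annotation["mito_fraction"].to_numpy() <= qc.max_mito_fraction))
    logger.info("filter_cells: removed %d of %d cells", int((~keep).sum()), counts.n_cells)
    return counts.subset_cells(np.flatnonzero(keep)), annotation.loc[keep].copy()


def filter_genes(counts: CountMatrix, min_cells_per_gene: int = 2) -> CountMatrix:
    """Keep genes detected (count > 0) in at least ``min_cells_per_gene`` cells."""
    cells_per_gene = np.diff(counts.values.indptr)  # csr: nonzeros per gene row
    keep = cells_per_gene >= min_cells_per_gene
    logger.info("filter_genes: removed %d of %d genes", int((~keep).sum()), counts.n_genes)
    return counts.subset_genes(np.flatnonzero(keep))


def normalize(counts: CountMatrix, scale: float = 10_000.0) -> NormMatrix:
    """Counts-per-``scale`` natural-log1p normalization.

    ``e(g,c) = ln(1 + scale * x(g,c) / T(c))`` with ``T(c)`` the cell total.
    Requires every cell to have at least one count (run :func:`filter_cells`
    first).  The zero pattern is preserved and the result is invariant to
    multiplying all counts of a cell by a constant.
    """
    totals = counts.umi_per_cell().astype(np.float64)
    if counts.n_cells and totals.min() <= 0:
        raise ValidationError(
            "all-zero cell present; apply filter_cells before normalize")
    csc = counts.values.tocsc().astype(np.float64)
    for c in range(counts.n_cells):  # per-column scaling on sparse data
        sl = slice(csc.indptr[c], csc.indptr[c + 1])
        csc.data[sl] = np.log1p(scale * csc.data[sl] / totals[c])
    return NormMatrix(csc.tocsr(), counts.gene_ids.copy(), counts.barcodes.copy(),
                      scale=scale, source_n_umi=totals)


def select_hvg(norm: NormMatrix, annotation: pd.DataFrame, n_top: int = 2000,
               grouping: str = "genotype", n_bins: int = 20,
               exclude_prefixes: tuple[str, ...] = ("MT-",)) -> list[str]:
    """Union of each group's top ``n_top`` highly variable genes.

    Within each group (genotype by default), genes are scored by dispersion
    (variance/mean of the normalized, de-logged expression, i.e. counts per
    10,000) z-scored within 20 equal-frequency mean bins; ties break
    lexicographically by gene id so selection is deterministic.
    Mitochondrial genes are excluded by default: their apparent dispersion
    tracks the per-cell mitochondrial-content covariate, not biology, and
    they crowd out real signal in the high-mean bins.
    """
    if n_top < 1:
        raise ValidationError("n_top must be >= 1")
    union: set[str] = set()
    keep = np.array([not str(g).startswith(exclude_prefixes)
                     for g in norm.gene_ids])
    gene_ids = norm.gene_ids[keep]
    groups = (annotation[grouping] if grouping in annotation.columns
              else pd.Series("all", index=annotation.index))
    for _, members in groups.groupby(groups, observed=True).groups.items():
        mask = annotation.index.get_indexer(members)
        sub = norm.values[keep][:, mask]
        scores = _binned_dispersion(sub, gene_ids, n_bins)
        union.update(scores.head(n_top).index.tolist())
    return sorted(union)


def _binned_dispersion(mat: sp.csr_matrix, gene_ids: np.ndarray,
                       n_bins: int) -> pd.Series:
    n_cells = mat.shape[1]
    delog = mat.copy()
    delog.data = np.expm1(delog.data)  # back to the counts-per-scale domain
    mean = np.asarray(delog.mean(axis=1)).ravel()
    sq = np.asarray(delog.multiply(delog).mean(axis=1)).ravel()
    var = np.maximum(sq - mean**2, 0.0) * (n_cells / max(n_cells - 1, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, np.log1p(var / np.where(mean > 0, mean, 1.0)),
                        np.nan)
    df = pd.DataFrame({"mean": mean, "disp": disp},
                      index=pd.Index(gene_ids)).dropna()
    df = df.sort_index()  # lexicographic base order = deterministic ties
    if len(df) < n_bins:
        warnings.warn(f"only {len(df)} usable genes; reducing bins from {n_bins}")
        n_bins = max(1, len(df))
    ranks = df["mean"].rank(method="first")
    df["bin"] = pd.qcut(ranks, q=n_bins, labels=False, duplicates="drop")
    z = df.groupby("bin")["disp"].transform(
        lambda d: (d - d.mean()) / (d.std(ddof=1) or 1.0) if len(d) > 1 else 0.0)
    z = z.fillna(0.0)
    order = pd.DataFrame({"z": z}).sort_values("z", ascending=False, kind="stable")
    return order["z"]
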