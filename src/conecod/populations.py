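"""Cell-population partitioning, marker annotation, and group statistics.

Covers four related jobs:

* unsupervised partitioning of cells (PCA on scaled variable genes followed
  by k-means),
* scoring clusters against marker panels (e.g. NR2E3/SAG for rods, ARR3 and
  the opsins for cones) and assigning population names,
* the per-gene expression-group triple — percent of cells expressing, mean
  normalized expression within expressers, and mean total normalized
  expression — with two-sided significance calls between genotypes,
* Spearman mapping of population mean profiles onto reference populations
  (fetal, adult peripheral, adult foveal), and relative qPCR quantification
  via ΔΔC(q).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import yaml
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .containers import CountMatrix, NormMatrix, ValidationError
from .synthetic import CqTable

logger = logging.getLogger(__name__)

# Default panels built from genes of the retinal literature; user panels
# (YAML: population -> gene list) override these entirely.
DEFAULT_MARKER_PANEL: dict[str, list[str]] = {
    "rod": ["NR2E3", "SAG", "GNAT1", "NRL", "ROM1", "CNGB1", "PDE6G", "SAMD7"],
    "ML-cone": ["OPN1MW", "ARR3", "PDE6H", "GNAT2", "GNGT2", "PDE6C", "GUCA1C",
                "MYL4"],
    "S-cone": ["OPN1SW", "CNGB3", "CCDC136", "ARR3", "PDE6H"],
    "cod": ["OPN1SW", "GNGT1"],
    "developing": ["CRX", "RCVRN", "OTX2", "NEUROD1", "PRDM1", "AIPL1", "RAX2",
                   "CRABP2"],
    "bipolar": ["VSX1", "VSX2", "CABP5", "GRM6", "PRKCA", "TRPM1", "GRIK1",
                "ISL1"],
    "amacrine": ["TFAP2A", "GAD1", "SLC32A1", "CALB2", "GAD2", "SLC6A9",
                 "CHAT", "TH"],
    "horizontal": ["ONECUT1", "ONECUT2", "LHX1", "CALB1", "NDNF", "TPBG"],
    "muller": ["RLBP1", "SLC1A3", "GLUL", "APOE", "CLU", "AQP4", "SOX9",
               "CRYM"],
    "RGC": ["RBPMS", "POU4F2", "SNCG", "NEFL", "GAP43", "THY1"],
}


class AnnotationError(ValueError):
    pass


def load_marker_panel(path) -> dict[str, list[str]]:
    """Marker panel from YAML: ``population: [gene, ...]``."""
    with open(path) as fh:
        panel = yaml.safe_load(fh)
    validate_marker_panel(panel)
    return panel


def validate_marker_panel(panel: dict[str, list[str]]) -> None:
    if not panel:
        raise ValidationError("marker panel is empty")
    for pop, genes in panel.items():
        if not genes:
            raise ValidationError(f"panel {pop} has no marker genes")
        if len(genes) != len(set(genes)):
            raise ValidationError(f"panel {pop} contains duplicate markers")


# ---------------------------------------------------------------------------
# Clustering + annotation
# ---------------------------------------------------------------------------

def cluster_cells(norm: NormMatrix, hvg: list[str], n_components: int = 20,
                  k: int = 10, seed: int = 0) -> np.ndarray:
    """PCA on z-scaled variable-gene expression, then k-means.

    Returns one integer cluster id per cell. Deterministic for a fixed seed.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > norm.n_cells:
        raise ValidationError(f"k={k} exceeds the number of cells ({norm.n_cells})")
    hvg_present = [g for g in hvg if g in norm.gene_index()]
    if not hvg_present:
        raise ValidationError("none of the requested genes are in the matrix")
    X = norm.dense(hvg_present).to_numpy().T  # cells x genes
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = np.clip((X - mu) / sd, -10, 10)
    n_components = min(n_components, min(X.shape) - 1) or 1
    pcs = PCA(n_components=n_components, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(pcs)


@dataclass
class ClusterAnnotation:
    """Population call per cluster with the full panel-score matrix."""

    population: dict[int, str]
    scores: pd.DataFrame                     # panels x clusters, mean marker z
    ambiguous: set[int] = field(default_factory=set)

    def per_cell(self, cluster_ids: np.ndarray) -> np.ndarray:
        return np.asarray([self.population[c] for c in cluster_ids], dtype=object)


def annotate_clusters(norm: NormMatrix, cluster_ids: np.ndarray,
                      panel: dict[str, list[str]] | None = None,
                      ) -> ClusterAnnotation:
    """Name each cluster after the marker panel it scores highest on.

    The score of panel P in cluster c is the mean, over P's markers, of the
    cluster-average expression z-scored against the gene's across-cell mean
    and standard deviation (so scores stay meaningful even with two
    clusters).  Ties break by panel name order and are flagged ambiguous.
    Missing markers warn; a panel with no marker present in the matrix at
    all is an error.
    """
    panel = panel or DEFAULT_MARKER_PANEL
    validate_marker_panel(panel)
    clusters = np.unique(cluster_ids)
    gene_idx = norm.gene_index()
    all_markers = sorted({g for genes in panel.values() for g in genes})
    present = [g for g in all_markers if g in gene_idx]
    missing = sorted(set(all_markers) - set(present))
    if missing:
        warnings.warn(f"markers absent from matrix (ignored): {missing}")
    if not present:
        raise AnnotationError("no marker panel gene is present in the matrix")

    expr = norm.dense(present)  # markers x cells
    cluster_mean = pd.DataFrame(
        {c: expr.iloc[:, np.flatnonzero(cluster_ids == c)].mean(axis=1)
         for c in clusters})
    cell_mean = expr.mean(axis=1)
    cell_sd = expr.std(axis=1, ddof=0).replace(0.0, 1.0)
    z = cluster_mean.sub(cell_mean, axis=0).div(cell_sd, axis=0)

    scores = pd.DataFrame(
        {c: {p: z.loc[[g for g in genes if g in z.index], c].mean()
             for p, genes in panel.items()} for c in clusters})
    scores = scores.sort_index()  # panel name order fixes tie-breaking

    population: dict[int, str] = {}
    ambiguous: set[int] = set()
    for c in clusters:
        col = scores[c]
        best = col.max()
        winners = col.index[col == best].tolist()
        population[int(c)] = winners[0]
        if len(winners) > 1:
            ambiguous.add(int(c))
    return ClusterAnnotation(population=population, scores=scores,
                             ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# Expression-group statistics
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSummary:
    """Per gene x group: % expressing, mean among expressers, mean overall.

    ``mean_total == mean_in_expressers * pct_expressing / 100`` by
    construction (means are of log-normalized expression; "expressing"
    means raw count above ``expr_threshold``, default 0).
    """

    gene: str
    group: str
    pct_expressing: float
    mean_in_expressers: float
    mean_total: float
    n_cells: int
    n_expressing: int


def expression_summary(raw: CountMatrix, norm: NormMatrix, gene: str,
                       mask: np.ndarray, group: str = "group",
                       expr_threshold: int = 0) -> ExpressionSummary:
    """Compute the expression-group triple for one gene over a cell mask."""
    mask = np.asarray(mask, dtype=bool)
    n_group = int(mask.sum())
    if n_group == 0:
        raise ValidationError("group mask selects no cells")
    gi = raw.gene_index().get_loc(gene)
    raw_vals = np.asarray(raw.values[gi].todense()).ravel()[mask]
    norm_vals = norm.gene_vector(gene)[mask]
    expressing = raw_vals > expr_threshold
    n_expr = int(expressing.sum())
    pct = 100.0 * n_expr / n_group
    mean_in = float(norm_vals[expressing].mean()) if n_expr else 0.0
    mean_total = float(norm_vals[expressing].sum() / n_group) if n_expr else 0.0
    return ExpressionSummary(gene=gene, group=group, pct_expressing=pct,
                             mean_in_expressers=mean_in, mean_total=mean_total,
                             n_cells=n_group, n_expressing=n_expr)


def summary_table(raw: CountMatrix, norm: NormMatrix, genes: list[str],
                  groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tidy frame of :func:`expression_summary` over genes x groups."""
    rows = []
    for gene in genes:
        for name, mask in groups.items():
            s = expression_summary(raw, norm, gene, mask, group=name)
            rows.append(vars(s))
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    p_proportion: float
    p_level: float
    level_defined: bool   # False when too few expressers to compare levels


def compare_expression_groups(raw: CountMatrix, norm: NormMatrix, gene: str,
                              mask_a: np.ndarray, mask_b: np.ndarray,
                              expr_threshold: int = 0) -> GroupComparison:
    """Two significance calls between groups for one gene.

    ``p_proportion``: two-sided two-proportion z-test on the expressing
    counts, replaced by Fisher's exact test when any expected cell count is
    below 5.  ``p_level``: two-sided Wilcoxon rank-sum on normalized
    expression among expressers only; undefined (reported as 1, flagged)
    when either side has no expresser.
    """
    a = expression_summary(raw, norm, gene, mask_a, "A", expr_threshold)
    b = expression_summary(raw, norm, gene, mask_b, "B", expr_threshold)
    x = np.array([a.n_expressing, b.n_expressing])
    n = np.array([a.n_cells, b.n_cells])
    p_pool = x.sum() / n.sum()
    expected = np.concatenate([n * p_pool, n * (1 - p_pool)])
    if (expected < 5).any():
        table = np.array([[x[0], n[0] - x[0]], [x[1], n[1] - x[1]]])
        p_prop = float(scipy.stats.fisher_exact(table)[1])
    elif x.sum() == 0 or x.sum() == n.sum():
        p_prop = 1.0
    else:
        from statsmodels.stats.proportion import proportions_ztest
        p_prop = float(proportions_ztest(x, n)[1])

    gi = raw.gene_index().get_loc(gene)
    raw_row = np.asarray(raw.values[gi].todense()).ravel()
    norm_row = norm.gene_vector(gene)
    va = norm_row[np.asarray(mask_a, bool) & (raw_row > expr_threshold)]
    vb = norm_row[np.asarray(mask_b, bool) & (raw_row > expr_threshold)]
    if len(va) == 0 or len(vb) == 0:
        return GroupComparison(p_prop, 1.0, level_defined=False)
    if np.array_equal(np.sort(va), np.sort(vb)):
        p_level = 1.0
    else:
        p_level = float(scipy.stats.mannwhitneyu(va, vb, alternative="two-sided",
                                                 method="asymptotic")[1])
    return GroupComparison(p_prop, p_level, level_defined=True)


# ---------------------------------------------------------------------------
# Reference-population Spearman mapping
# ---------------------------------------------------------------------------

@dataclass
class ReferenceProfile:
    """Named per-gene mean expression vector (e.g. adult foveal cones)."""

    name: str
    values: pd.Series
    source: str = ""

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError(f"reference {self.name} has duplicate gene ids")
        if (self.values < 0).any():
            raise ValidationError(f"reference {self.name} has negative values")


def load_reference_profiles(path) -> list[ReferenceProfile]:
    """TSV with genes as rows and one column per reference population."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [ReferenceProfile(name=c, values=df[c].dropna()) for c in df.columns]


def refmap_spearman(query: pd.Series,
                    references: list[ReferenceProfile]) -> pd.DataFrame:
    """Spearman rho of a population mean profile against each reference.

    Computed over the gene intersection (>= 3 genes required); the returned
    frame is sorted by rho, best match first.
    """
    rows = []
    for ref in references:
        shared = query.index.intersection(ref.values.index)
        if len(shared) < 3:
            raise ValidationError(
                f"only {len(shared)} genes shared with reference {ref.name}")
        rho, p = scipy.stats.spearmanr(query.loc[shared], ref.values.loc[shared])
        rows.append({"reference": ref.name, "source": ref.source,
                     "n_genes": len(shared), "rho": float(rho), "p": float(p)})
    return (pd.DataFrame(rows)
            .sort_values("rho", ascending=False)
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# qPCR ΔΔC(q)
# ---------------------------------------------------------------------------

def ddcq_fold_change(cq: CqTable, reference_condition: str = "WT",
                     housekeeping_combine: str = "geometric") -> pd.DataFrame:
    """Relative quantification: per-gene fold change 2^-ΔΔC(q) + Mann-Whitney p.

    ΔC(q) of a target in a sample is its mean Cq minus the combination of
    the two housekeeping genes' mean Cq values — geometric mean by default,
    arithmetic behind the flag (the latter equals the geometric mean of the
    housekeeping genes' linear abundances).  ΔΔC(q) subtracts the average
    reference-condition ΔC(q); the reported fold is ``2 ** -mean(ΔΔC(q))``
    over test-condition samples, and p compares per-sample ΔC(q) between
    conditions with a two-sided Mann-Whitney test.
    """
    if housekeeping_combine not in ("geometric", "arithmetic"):
        raise ValidationError("housekeeping_combine must be geometric|arithmetic")
    data = cq.data
    hk1, hk2 = cq.housekeeping
    mean_cq = (data.groupby(["sample", "condition", "gene"], observed=True)["cq"]
               .mean().reset_index())
    wide = mean_cq.pivot_table(index=["sample", "condition"], columns="gene",
                               values="cq")
    for hk in (hk1, hk2):
        if hk not in wide.columns or wide[hk].isna().any():
            raise ValidationError(f"housekeeping gene {hk} missing in a sample")
    if housekeeping_combine == "geometric":
        hk_ref = np.sqrt(wide[hk1] * wide[hk2])
    else:
        hk_ref = (wide[hk1] + wide[hk2]) / 2.0
    targets = [g for g in wide.columns if g not in (hk1, hk2)]
    conditions = wide.index.get_level_values("condition")
    if reference_condition not in set(conditions):
        raise ValidationError(f"no samples with condition {reference_condition}")
    rows = []
    for gene in targets:
        dcq = wide[gene] - hk_ref
        ref_vals = dcq[conditions == reference_condition].dropna()
        test_vals = dcq[conditions != reference_condition].dropna()
        ddcq = test_vals - ref_vals.mean()
        fold = float(2.0 ** (-ddcq.mean())) if len(test_vals) else np.nan
        if len(ref_vals) >= 2 and len(test_vals) >= 2:
            if np.array_equal(np.sort(ref_vals), np.sort(test_vals)):
                p = 1.0
            else:
                p = float(scipy.stats.mannwhitneyu(
                    test_vals, ref_vals, alternative="two-sided")[1])
        else:
            p = np.nan
        rows.append({"gene": gene, "fold_change": fold,
                     "log2_fold": float(np.log2(fold)) if fold == fold else np.nan,
                     "p_mannwhitney": p,
                     "n_reference": len(ref_vals), "n_test": len(test_vals)})
    return pd.DataFrame(rows).set_index("gene")
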