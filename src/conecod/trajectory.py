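"""Branch-aware pseudotime over population centroids and NB count-model tests.

Ordering genes are selected by a semi-supervised negative-binomial
likelihood-ratio test: for every gene, a log-linear NB model with a group
indicator (age x coarse cell type, where NR2E3+ = rod, ARR3+ = cone,
neither = undifferentiated photoreceptor) and a log-total-count offset is
compared to the offset-only null.  The top genes by p-value — after
dropping ribosomal (RPL*/RPS*) and mitochondrial (MT-*) genes, 780 by
default — order the trajectory.

The trajectory itself is deliberately simple: low-dimensional PCA on
ordering-gene expression, k-means centroids, a minimum spanning tree over
centroid distances, the root at the least-mature centroid, pseudotime as
root-geodesic arc length of each cell's projection onto its nearest tree
edge, and states as the path-equivalence classes the branch nodes
induce.  Branch-node differential expression reuses the same NB
likelihood-ratio test with the branch as the group indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from scipy.special import gammaln
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, NormMatrix, ValidationError

RIBO_PREFIXES = ("RPL", "RPS")
MITO_PREFIX = "MT-"
DEFAULT_MATURITY_MARKERS = ["NR2E3", "SAG", "OPN1SW", "OPN1MW", "ARR3",
                            "GNAT1", "PDE6H"]
# retinal progenitor genes: high where the lineage starts, so they break
# ties between equally opsin-negative candidate roots
DEFAULT_IMMATURITY_MARKERS = ["NES", "SOX2", "PAX6", "LHX2", "HES1", "ASCL1",
                              "MKI67", "SOX4", "SOX11"]


@dataclass
class OrderingConfig:
    """Ordering-gene selection parameters."""

    n_ordering_genes: int = 780
    exclude_prefixes: tuple[str, ...] = RIBO_PREFIXES + (MITO_PREFIX,)
    de_universe_min_cells: int = 10
    dispersion_floor: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_ordering_genes < 2:
            raise ValidationError("n_ordering_genes must be >= 2")


# ---------------------------------------------------------------------------
# Negative-binomial likelihood-ratio test (vectorized over genes)
# ---------------------------------------------------------------------------

def _mom_dispersion(counts: np.ndarray, totals: np.ndarray,
                    floor: float = 1e-8) -> np.ndarray:
    """Method-of-moments per-gene dispersion under a common-rate model.

    ``counts`` is genes x cells; the fitted mean of gene g in cell i is
    ``totals_i * rate_g``.  Dispersion solves
    ``sum((x - mu)^2 - mu) = phi * sum(mu^2)``, floored.
    """
    rate = counts.sum(axis=1) / totals.sum()
    mu = rate[:, None] * totals[None, :]
    num = ((counts - mu) ** 2 - mu).sum(axis=1)
    den = (mu ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(den > 0, num / np.where(den > 0, den, 1.0), floor)
    return np.maximum(phi, floor)


def _nb_loglik(x: np.ndarray, mu: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; x, mu are genes x cells, r per gene."""
    r = r[:, None]
    return (gammaln(x + r) - gammaln(r) - gammaln(x + 1)
            + r * np.log(r / (r + mu)) + x * np.log(mu / (r + mu) + 1e-300)
            ).sum(axis=1)


def _fit_log_mean(x: np.ndarray, totals: np.ndarray, r: np.ndarray,
                  n_iter: int = 50) -> np.ndarray:
    """Newton solve of the NB log-link MLE ``mu_i = t_i * exp(b)`` per gene.

    The log-likelihood is concave in b, so undamped Newton from the
    moment start ``b0 = log(sum x / sum t)`` converges; genes with all-zero
    counts get b = -inf (mu -> 0 handled by the caller).
    """
    sums = x.sum(axis=1)
    with np.errstate(divide="ignore"):
        b = np.log(sums / totals.sum())
    active = sums > 0
    for _ in range(n_iter):
        mu = np.exp(b[:, None]) * totals[None, :]
        rr = r[:, None]
        score = (x - (x + rr) * mu / (mu + rr)).sum(axis=1)
        info = ((x + rr) * rr * mu / (mu + rr) ** 2).sum(axis=1)
        step = np.where(active & (info > 0), score / np.maximum(info, 1e-12), 0.0)
        b = b + np.clip(step, -5, 5)
        if np.max(np.abs(step[active]), initial=0.0) < 1e-10:
            break
    return b


def nb_lrt(counts: np.ndarray, groups: np.ndarray, totals: np.ndarray,
           dispersion_floor: float = 1e-8) -> pd.DataFrame:
    """Per-gene NB likelihood-ratio test of a group effect.

    ``counts``: genes x cells integer array; ``groups``: one label per
    cell; ``totals``: per-cell total counts (the offset is ``log totals``).
    The gene-wise dispersion is estimated once by method of moments under
    the null and held fixed in both models, so the statistic is a clean
    likelihood ratio with ``n_groups - 1`` degrees of freedom.
    """
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if counts.shape[1] != len(groups) or len(totals) != len(groups):
        raise ValidationError("counts, groups and totals are not aligned")
    labels = pd.unique(pd.Series(groups))
    if len(labels) < 2:
        raise ValidationError("need at least two groups")
    phi = _mom_dispersion(counts, totals, floor=dispersion_floor)
    r = 1.0 / phi

    b0 = _fit_log_mean(counts, totals, r)
    mu0 = np.exp(b0[:, None]) * totals[None, :]
    ll0 = _nb_loglik(counts, np.maximum(mu0, 1e-300), r)

    ll1 = np.zeros(counts.shape[0])
    group_means = {}
    for lab in labels:
        sel = np.asarray(groups) == lab
        bg = _fit_log_mean(counts[:, sel], totals[sel], r)
        mug = np.exp(bg[:, None]) * totals[sel][None, :]
        ll1 += _nb_loglik(counts[:, sel], np.maximum(mug, 1e-300), r)
        group_means[str(lab)] = np.exp(bg)
    lr = np.maximum(2.0 * (ll1 - ll0), 0.0)
    p = scipy.stats.chi2.sf(lr, df=len(labels) - 1)
    out = pd.DataFrame({"lr": lr, "p": p})
    for lab, m in group_means.items():
        out[f"rate_{lab}"] = m
    return out


# ---------------------------------------------------------------------------
# Ordering-gene selection
# ---------------------------------------------------------------------------

def _excluded(gene: str, prefixes: tuple[str, ...]) -> bool:
    return any(str(gene).startswith(p) for p in prefixes)


def select_ordering_genes(raw: CountMatrix, labels: pd.DataFrame,
                          config: OrderingConfig | None = None) -> list[str]:
    """Rank genes by the semi-supervised NB LRT and return the top set.

    ``labels`` must carry ``age_day`` and ``coarse_type`` columns; the test
    groups cells by their combination.  Groups with fewer than 2 cells are
    dropped with a warning.  Ribosomal and mitochondrial genes never
    appear in the output.
    """
    config = config or OrderingConfig()
    if len(labels) != raw.n_cells:
        raise ValidationError("labels are not aligned to the count matrix")
    group = (labels["age_day"].astype(str) + ":" +
             labels["coarse_type"].astype(str)).to_numpy()
    sizes = pd.Series(group).value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"dropping groups with < 2 cells: {small}")
        keep = ~np.isin(group, small)
    else:
        keep = np.ones(len(group), dtype=bool)
    if pd.Series(group[keep]).nunique() < 2:
        raise ValidationError("need >= 2 usable (age x type) groups")

    sub = raw.values[:, np.flatnonzero(keep)].tocsr()
    detected = np.diff(sub.indptr)
    universe = np.flatnonzero(detected >= config.de_universe_min_cells)
    totals = np.asarray(sub.sum(axis=0)).ravel().astype(float)
    res = nb_lrt(sub[universe].toarray(), group[keep], totals,
                 dispersion_floor=config.dispersion_floor)
    res["gene"] = raw.gene_ids[universe]
    res = res[~res["gene"].map(lambda g: _excluded(g, config.exclude_prefixes))]
    res = res.sort_values(["p", "gene"], kind="stable")
    return res["gene"].head(config.n_ordering_genes).tolist()


def coarse_type_labels(raw: CountMatrix, rod_marker: str = "NR2E3",
                       cone_marker: str = "ARR3") -> pd.Series:
    """Marker-presence typing: rod if the rod marker is detected, cone if the
    cone marker is (rod wins when both), undifferentiated otherwise."""
    idx = raw.gene_index()
    rod = (np.asarray(raw.values[idx.get_loc(rod_marker)].todense()).ravel() > 0
           if rod_marker in idx else np.zeros(raw.n_cells, bool))
    cone = (np.asarray(raw.values[idx.get_loc(cone_marker)].todense()).ravel() > 0
            if cone_marker in idx else np.zeros(raw.n_cells, bool))
    out = np.where(rod, "rod", np.where(cone, "cone", "undifferentiated"))
    return pd.Series(out, index=pd.Index(raw.barcodes, name="barcode"),
                     name="coarse_type")


# ---------------------------------------------------------------------------
# Trajectory construction
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryResult:
    """Per-cell pseudotime/state/branch plus the centroid MST."""

    pseudotime: np.ndarray
    state: np.ndarray                 # state id per cell
    branch: np.ndarray                # trunk / branch-1 / branch-2 / ...
    centroid_of_cell: np.ndarray
    mst_edges: list[tuple[int, int, float]]
    root: int
    centroid_pseudotime: np.ndarray
    centroid_state: np.ndarray
    centroids: np.ndarray = field(repr=False)

    def cells_in_states(self, states) -> np.ndarray:
        return np.isin(self.state, list(states))


def build_trajectory(norm: NormMatrix, ordering_genes: list[str],
                     n_centroids: int = 12, root: int | None = None,
                     maturity_markers: list[str] | None = None,
                     n_components: int = 4, smooth_neighbors: int = 50,
                     seed: int = 0) -> TrajectoryResult:
    """Centroid-MST pseudotime on ordering-gene expression.

    PCA to ``n_components`` (default 4 — a bifurcating lineage is
    intrinsically low-dimensional and extra components only add isotropic
    noise to centroid distances), k-means to ``n_centroids`` centroids,
    minimum spanning tree over centroid Euclidean distances.  The root
    defaults to the centroid with the lowest mean maturity-marker
    expression (opsins, NR2E3, SAG ... — immature photoreceptors score
    low), restricted to tree endpoints — a lineage origin is never an
    interior node; pass ``root`` to override.  Before fitting, each cell's
    embedding is denoised by averaging with its ``smooth_neighbors``
    nearest neighbors (0 disables).  Each cell is projected onto its
    nearest tree edge; its pseudotime is the root-geodesic arc length at
    the projection, shifted so the minimum is 0 (projections may run past
    the root and leaf centroids so end segments keep their ordering).
    States are the maximal tree segments delimited by branch (degree >= 3)
    nodes; branch labels split cells where the paths to the two dominant
    fates diverge.
    """
    if n_centroids < 3:
        raise ValidationError("n_centroids must be >= 3")
    genes = [g for g in ordering_genes if g in norm.gene_index()]
    if len(genes) < 2:
        raise ValidationError("need at least two ordering genes in the matrix")
    X = norm.dense(genes).to_numpy().T  # cells x genes
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    n_components = max(1, min(n_components, min(X.shape) - 1))
    pcs = PCA(n_components=n_components, random_state=seed).fit_transform(X)
    if smooth_neighbors and len(pcs) > smooth_neighbors:
        nn = NearestNeighbors(n_neighbors=smooth_neighbors).fit(pcs)
        _, nn_idx = nn.kneighbors(pcs)
        pcs = pcs[nn_idx].mean(axis=1)
    n_centroids = min(n_centroids, len(pcs))
    km = KMeans(n_clusters=n_centroids, random_state=seed, n_init=30).fit(pcs)
    centroids = km.cluster_centers_
    assign = km.labels_

    dist = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=2)
    mst = minimum_spanning_tree(dist).toarray()
    adj = np.maximum(mst, mst.T)
    edges = [(int(i), int(j), float(adj[i, j]))
             for i in range(n_centroids) for j in range(i + 1, n_centroids)
             if adj[i, j] > 0]

    if root is None:
        degree_all = (adj > 0).sum(axis=1)
        leaves = np.flatnonzero(degree_all <= 1)
        root = _default_root(norm, assign, n_centroids,
                             maturity_markers or DEFAULT_MATURITY_MARKERS,
                             candidates=leaves)
    if not 0 <= root < n_centroids:
        raise ValidationError(f"root {root} outside 0..{n_centroids - 1}")

    geo = shortest_path(sp.csr_matrix(adj), directed=False, indices=root)
    parent = _parents(adj, root)
    degree = (adj > 0).sum(axis=1)

    # project every cell onto its nearest oriented (parent -> child) edge
    pt = np.zeros(len(pcs))
    node_of_cell = np.zeros(len(pcs), dtype=int)
    best_d = np.full(len(pcs), np.inf)
    for child in range(n_centroids):
        par = parent[child]
        if par < 0:
            continue
        a, b = centroids[par], centroids[child]
        ab = b - a
        length_sq = float(ab @ ab)
        if length_sq == 0:
            continue
        s = ((pcs - a) @ ab) / length_sq
        lo = -np.inf if par == root and degree[root] <= 1 else 0.0
        hi = np.inf if degree[child] <= 1 else 1.0
        s = np.clip(s, lo, hi)
        proj = a + s[:, None] * ab
        d = np.linalg.norm(pcs - proj, axis=1)
        upd = d < best_d
        best_d[upd] = d[upd]
        pt[upd] = geo[par] + s[upd] * np.sqrt(length_sq)
        # an edge is downstream territory of its child: any cell past the
        # parent centroid has entered the child's segment
        node_of_cell[upd] = child
    if len(pt):
        pt = pt - pt.min()

    centroid_state, _ = _states(adj, parent, root, assign)
    state_of_cell = centroid_state[node_of_cell]
    branch = _branch_labels(adj, parent, root, node_of_cell, geo)
    return TrajectoryResult(
        pseudotime=pt, state=state_of_cell, branch=branch,
        centroid_of_cell=assign, mst_edges=edges, root=int(root),
        centroid_pseudotime=geo, centroid_state=centroid_state,
        centroids=centroids)


def _default_root(norm: NormMatrix, assign: np.ndarray, n_centroids: int,
                  markers: list[str],
                  candidates: np.ndarray | None = None) -> int:
    """Least-mature candidate centroid: low maturity-marker expression,
    high progenitor expression."""
    present = [g for g in markers if g in norm.gene_index()]
    immature = [g for g in DEFAULT_IMMATURITY_MARKERS if g in norm.gene_index()]
    pool = (np.asarray(candidates) if candidates is not None and
            len(candidates) else np.arange(n_centroids))
    if not present and not immature:
        return int(pool[0])
    expr = (norm.dense(present).to_numpy().mean(axis=0) if present
            else np.zeros(norm.n_cells))
    if immature:
        expr = expr - norm.dense(immature).to_numpy().mean(axis=0)
    score = np.array([expr[assign == c].mean() if (assign == c).any() else np.inf
                      for c in pool])
    return int(pool[int(np.argmin(score))])


def _parents(adj: np.ndarray, root: int) -> np.ndarray:
    n = adj.shape[0]
    parent = np.full(n, -1, dtype=int)
    seen = {root}
    stack = [root]
    while stack:
        u = stack.pop()
        for v in np.flatnonzero(adj[u] > 0):
            if v not in seen:
                parent[v] = u
                seen.add(int(v))
                stack.append(int(v))
    return parent


def _states(adj: np.ndarray, parent: np.ndarray, root: int,
            assign: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Path-equivalence state per centroid: a new state opens after every
    branch (degree >= 3) node on the way out from the root."""
    n = adj.shape[0]
    degree = (adj > 0).sum(axis=1)
    state = np.full(n, -1, dtype=int)
    next_state = 0
    order = _bfs_order(adj, root)
    for u in order:
        if parent[u] < 0:
            state[u] = next_state
            next_state += 1
        elif degree[parent[u]] >= 3:
            state[u] = next_state
            next_state += 1
        else:
            state[u] = state[parent[u]]
    return state, state[assign]


def _path_to_root(parent: np.ndarray, node: int) -> list[int]:
    path = [node]
    while parent[path[-1]] >= 0:
        path.append(int(parent[path[-1]]))
    return path[::-1]  # root ... node


def _branch_labels(adj: np.ndarray, parent: np.ndarray, root: int,
                   assign: np.ndarray, geo: np.ndarray) -> np.ndarray:
    """Label centroids trunk / branch-1 / branch-2 by the dominant fates.

    The two fates are the leaves farthest from the root whose root paths
    diverge; the branch node is where those paths split.  Centroids beyond
    the branch node toward either fate get branch labels; everything else —
    the shared path and any noise twigs — stays trunk.
    """
    n = adj.shape[0]
    degree = (adj > 0).sum(axis=1)
    leaves = [u for u in range(n) if degree[u] <= 1 and u != root]
    label = np.full(n, "trunk", dtype=object)
    if len(leaves) >= 2:
        leaf1 = max(leaves, key=lambda u: geo[u])
        path1 = _path_to_root(parent, leaf1)
        on1 = set(path1)

        def arm_length(u: int) -> float:
            # geodesic from u back to where its root path meets path1
            path = _path_to_root(parent, u)
            lca = [v for v in path if v in on1][-1]
            return geo[u] - geo[lca]

        divergent = [u for u in leaves if u not in on1]
        if divergent:
            leaf2 = max(divergent, key=arm_length)
            path2 = _path_to_root(parent, leaf2)
            shared = 0
            while (shared < min(len(path1), len(path2))
                   and path1[shared] == path2[shared]):
                shared += 1
            # path1[shared - 1] is the branch node
            for bi, path in ((1, path1), (2, path2)):
                for u in path[shared:]:
                    for v in _subtree(parent, u):
                        if label[v] == "trunk":
                            label[v] = f"branch-{bi}"
    return label[assign]


def _subtree(parent: np.ndarray, node: int) -> list[int]:
    children: dict[int, list[int]] = {}
    for v, p in enumerate(parent):
        children.setdefault(int(p), []).append(v)
    out, stack = [], [node]
    while stack:
        u = stack.pop()
        out.append(u)
        stack.extend(children.get(u, []))
    return out


def _bfs_order(adj: np.ndarray, root: int) -> list[int]:
    from collections import deque
    seen = {root}
    order = []
    queue = deque([root])
    while queue:
        u = queue.popleft()
        order.append(u)
        for v in np.flatnonzero(adj[u] > 0):
            if v not in seen:
                seen.add(int(v))
                queue.append(int(v))
    return order


# ---------------------------------------------------------------------------
# Branch-node differential expression
# ---------------------------------------------------------------------------

def branch_de(raw: CountMatrix, trajectory: TrajectoryResult,
              branch_a_states, branch_b_states, top_n: int = 100,
              de_universe_min_cells: int = 10) -> pd.DataFrame:
    """NB likelihood-ratio DE between two sets of trajectory states.

    Returns all tested genes with p, BH q, and per-branch fitted rates; the
    boolean ``top`` column marks the ``top_n`` non-ribosomal genes by p
    (the heatmap set).
    """
    in_a = trajectory.cells_in_states(branch_a_states)
    in_b = trajectory.cells_in_states(branch_b_states)
    if not in_a.any() or not in_b.any():
        raise ValidationError("both branches must contain at least one cell")
    if (in_a & in_b).any():
        raise ValidationError("branch state sets overlap")
    mask = in_a | in_b
    sub = raw.values[:, np.flatnonzero(mask)].tocsr()
    detected = np.diff(sub.indptr)
    universe = np.flatnonzero(detected >= de_universe_min_cells)
    totals = np.asarray(sub.sum(axis=0)).ravel().astype(float)
    groups = np.where(in_a[mask], "A", "B")
    res = nb_lrt(sub[universe].toarray(), groups, totals)
    res["gene"] = raw.gene_ids[universe]
    res["q"] = multipletests(res["p"], method="fdr_bh")[1]
    res = res.sort_values(["p", "gene"], kind="stable").reset_index(drop=True)
    non_ribo = ~res["gene"].map(lambda g: _excluded(g, RIBO_PREFIXES))
    top_genes = set(res.loc[non_ribo, "gene"].head(top_n))
    res["top"] = res["gene"].isin(top_genes)
    return res[["gene", "lr", "p", "q", "rate_A", "rate_B", "top"]]
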