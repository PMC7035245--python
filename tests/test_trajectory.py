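import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats

import conecod
from conecod import qc, trajectory
from conecod.containers import CountMatrix, NormMatrix, ValidationError

from conftest import branch_accuracy


def grid_lrt_p(counts, groups, totals, floor=1e-8):
    """Oracle: grid-maximized NB likelihood ratio for one gene."""
    counts = np.asarray(counts, dtype=float)[None, :]
    phi = trajectory._mom_dispersion(counts, totals, floor=floor)
    r = np.array([1.0 / phi[0]])

    def best_ll(x, t):
        start = np.log(max(x.sum(), 1e-9) / t.sum())
        grid = start + np.linspace(-2, 2, 4001)
        lls = [trajectory._nb_loglik(x[None, :],
                                     np.exp(b) * t[None, :], r)[0]
               for b in grid]
        return max(lls)

    ll0 = best_ll(counts[0], totals)
    ll1 = 0.0
    labels = pd.unique(pd.Series(groups))
    for lab in labels:
        sel = np.asarray(groups) == lab
        ll1 += best_ll(counts[0][sel], totals[sel])
    lr = max(0.0, 2.0 * (ll1 - ll0))
    return scipy.stats.chi2.sf(lr, df=len(labels) - 1)


class TestNbLrt:
    def test_matches_grid_maximized_likelihood(self):
        """Newton-fitted LR p agrees with a brute-force grid oracle on 20
        random small instances."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 51))
            totals = rng.integers(50, 300, size=n).astype(float)
            groups = rng.choice(["a", "b"], size=n)
            if len(set(groups)) < 2:
                groups[0], groups[1] = "a", "b"
            rate = 0.02 * (1 + 2 * (groups == "a"))
            counts = rng.poisson(rate * totals)
            if counts.sum() == 0:
                counts[0] = 1
            p_fit = trajectory.nb_lrt(counts[None, :], groups, totals)["p"][0]
            p_grid = grid_lrt_p(counts, groups, totals)
            assert p_fit == pytest.approx(p_grid, abs=1e-3)

    def test_requires_two_groups(self):
        with pytest.raises(ValidationError):
            trajectory.nb_lrt(np.ones((1, 4)), ["a"] * 4, np.ones(4))


class TestSelectOrderingGenes:
    def _counts(self, arr, genes):
        return CountMatrix(sp.csr_matrix(arr.astype(np.int64)),
                           np.asarray(genes, dtype=object),
                           np.asarray([f"C{i}" for i in range(arr.shape[1])],
                                      dtype=object))

    def test_ribosomal_gene_excluded_despite_strong_effect(self):
        rng = np.random.default_rng(1)
        n = 120
        group = np.array(["rod"] * 60 + ["cone"] * 60)
        base = rng.poisson(2.0, size=(30, n))
        rpl3 = np.where(group == "rod", rng.poisson(30.0, n),
                        rng.poisson(1.0, n))
        arr = np.vstack([base, rpl3])
        genes = [f"G{i:02d}" for i in range(30)] + ["RPL3"]
        counts = self._counts(arr, genes)
        labels = pd.DataFrame({"age_day": 100, "coarse_type": group})
        out = trajectory.select_ordering_genes(
            counts, labels, trajectory.OrderingConfig(n_ordering_genes=31))
        assert "RPL3" not in out

    def test_spike_in_recovery(self):
        """Genes with a 4-fold group effect among null genes dominate the
        top of the ranking."""
        rng = np.random.default_rng(2)
        n = 300
        group = np.array(["rod"] * 150 + ["cone"] * 150)
        null = rng.poisson(1.0, size=(2000, n))
        effect = np.where(group == "rod",
                          rng.poisson(4.0, size=(50, n)),
                          rng.poisson(1.0, size=(50, n)))
        arr = np.vstack([null, effect])
        genes = ([f"N{i:04d}" for i in range(2000)]
                 + [f"S{i:02d}" for i in range(50)])
        counts = self._counts(arr, genes)
        labels = pd.DataFrame({"age_day": 100, "coarse_type": group})
        top100 = trajectory.select_ordering_genes(
            counts, labels, trajectory.OrderingConfig(n_ordering_genes=100))
        assert sum(g.startswith("S") for g in top100) >= 45

    def test_null_type_one_error_calibrated(self):
        """Identical groups give approximately uniform p-values."""
        rejections, total = 0, 0
        for seed in range(4):
            rng = np.random.default_rng(10 + seed)
            n = 200
            group = rng.choice(["a", "b"], size=n)
            arr = rng.poisson(1.5, size=(500, n))
            totals = arr.sum(axis=0).astype(float)
            res = trajectory.nb_lrt(arr, group, totals)
            rejections += int((res["p"] < 0.05).sum())
            total += len(res)
        assert 0.03 <= rejections / total <= 0.07


def line_norm(n_cells=200, n_genes=5):
    """Noiseless 1-D limit: normalized expression exactly linear in the
    cell's position, so the trajectory lives on a straight line."""
    pos = np.linspace(0, 1, n_cells)
    arr = np.vstack([0.1 + pos * (g + 1) for g in range(n_genes)])
    norm = NormMatrix(sp.csr_matrix(arr),
                      np.asarray([f"G{i}" for i in range(n_genes)],
                                 dtype=object),
                      np.asarray([f"C{i}" for i in range(n_cells)],
                                 dtype=object))
    return norm, pos


class TestBuildTrajectory:
    def test_noiseless_line_recovers_exact_order(self):
        norm, pos = line_norm()
        traj = trajectory.build_trajectory(norm, [f"G{i}" for i in range(5)],
                                           n_centroids=5, root=None,
                                           maturity_markers=["G0"],
                                           smooth_neighbors=0, seed=0)
        rho = scipy.stats.spearmanr(traj.pseudotime, pos)[0]
        assert rho == pytest.approx(1.0)
        assert traj.pseudotime.min() == 0.0

    def test_forcing_root_to_far_leaf_reverses_order(self):
        norm, pos = line_norm()
        traj = trajectory.build_trajectory(norm, [f"G{i}" for i in range(5)],
                                           n_centroids=5,
                                           maturity_markers=["G0"],
                                           smooth_neighbors=0, seed=0)
        far_leaf = int(np.argmax(traj.centroid_pseudotime))
        rev = trajectory.build_trajectory(norm, [f"G{i}" for i in range(5)],
                                          n_centroids=5, root=far_leaf,
                                          smooth_neighbors=0, seed=0)
        rho = scipy.stats.spearmanr(rev.pseudotime, pos)[0]
        assert rho == pytest.approx(-1.0, abs=1e-6)

    def test_minimum_centroid_count(self, bifurcation_dataset):
        with pytest.raises(ValidationError):
            trajectory.build_trajectory(bifurcation_dataset["norm"],
                                        ["NR2E3", "ARR3"], n_centroids=2)

    def test_centroid_pseudotime_monotone_to_root(self, bifurcation_dataset):
        data = bifurcation_dataset
        genes = trajectory.select_ordering_genes(
            data["raw"], data["labels"],
            trajectory.OrderingConfig(n_ordering_genes=60))
        traj = trajectory.build_trajectory(data["norm"], genes, seed=0)
        geo = traj.centroid_pseudotime
        assert geo[traj.root] == 0.0
        # walking toward the root always decreases geodesic pseudotime
        parent = trajectory._parents(
            _adjacency(traj), traj.root)
        for node, par in enumerate(parent):
            if par >= 0:
                assert geo[node] > geo[par]


def _adjacency(traj):
    n = len(traj.centroid_pseudotime)
    adj = np.zeros((n, n))
    for a, b, d in traj.mst_edges:
        adj[a, b] = adj[b, a] = d
    return adj


class TestBranchDe:
    def test_branch_specific_genes_recovered(self, bifurcation_dataset):
        data = bifurcation_dataset
        genes = trajectory.select_ordering_genes(
            data["raw"], data["labels"],
            trajectory.OrderingConfig(n_ordering_genes=60))
        traj = trajectory.build_trajectory(data["norm"], genes, seed=0)
        states_a = sorted(set(traj.state[traj.branch == "branch-1"]))
        states_b = sorted(set(traj.state[traj.branch == "branch-2"]))
        table = trajectory.branch_de(data["raw"], traj, states_a, states_b,
                                     top_n=40)
        top = set(table.loc[table["top"], "gene"])
        rod = {g for g, _ in
               conecod.synthetic.DEFAULT_MARKER_PROGRAM["rod"]}
        cone = {g for g, _ in
                conecod.synthetic.DEFAULT_MARKER_PROGRAM["ML-cone"]}
        assert len(top & rod) >= 8 and len(top & cone) >= 8
        # directions are coherent: rod genes enriched on one branch,
        # cone genes on the other
        sub = table.set_index("gene")
        rod_dir = np.sign(np.log(sub.loc[sorted(top & rod), "rate_A"]
                                 / sub.loc[sorted(top & rod), "rate_B"]))
        cone_dir = np.sign(np.log(sub.loc[sorted(top & cone), "rate_A"]
                                  / sub.loc[sorted(top & cone), "rate_B"]))
        assert len(set(rod_dir)) == 1 and len(set(cone_dir)) == 1
        assert rod_dir.iloc[0] != cone_dir.iloc[0]

    def test_null_branches_calibrated(self):
        rng = np.random.default_rng(3)
        arr = rng.poisson(1.5, size=(400, 160))
        counts = CountMatrix(sp.csr_matrix(arr.astype(np.int64)),
                             np.asarray([f"G{i:03d}" for i in range(400)],
                                        dtype=object),
                             np.asarray([f"C{i}" for i in range(160)],
                                        dtype=object))
        fake = trajectory.TrajectoryResult(
            pseudotime=np.zeros(160),
            state=np.array([0] * 80 + [1] * 80),
            branch=np.array(["branch-1"] * 80 + ["branch-2"] * 80,
                            dtype=object),
            centroid_of_cell=np.zeros(160, int), mst_edges=[], root=0,
            centroid_pseudotime=np.zeros(2), centroid_state=np.arange(2),
            centroids=np.zeros((2, 2)))
        table = trajectory.branch_de(counts, fake, [0], [1])
        frac = (table["p"] < 0.05).mean()
        assert 0.02 <= frac <= 0.09

    def test_top_n_zero_keeps_full_table(self, bifurcation_dataset):
        data = bifurcation_dataset
        traj = trajectory.build_trajectory(
            data["norm"], list(data["norm"].gene_ids[:50]), seed=0)
        states = sorted(set(traj.state))
        table = trajectory.branch_de(data["raw"], traj, states[:1],
                                     states[1:2], top_n=0)
        assert len(table) > 0 and not table["top"].any()

    def test_overlapping_branches_rejected(self, bifurcation_dataset):
        data = bifurcation_dataset
        traj = trajectory.build_trajectory(
            data["norm"], list(data["norm"].gene_ids[:50]), seed=0)
        states = sorted(set(traj.state))
        with pytest.raises(ValidationError):
            trajectory.branch_de(data["raw"], traj, states[:1], states[:1])
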