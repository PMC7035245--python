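import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

import conecod
from conecod import populations, qc
from conecod.containers import CountMatrix, NormMatrix, ValidationError
from conecod.populations import AnnotationError

from conftest import run_qc


def norm_from_array(arr, genes):
    counts = CountMatrix(sp.csr_matrix(np.asarray(arr, dtype=np.int64)),
                         np.asarray(genes, dtype=object),
                         np.asarray([f"C{i}" for i in range(arr.shape[1])],
                                    dtype=object))
    return counts, qc.normalize(counts)


class TestClusterCells:
    def test_k_below_two_rejected(self, organoid_dataset):
        with pytest.raises(ValidationError):
            populations.cluster_cells(organoid_dataset["norm"], ["NR2E3"], k=1)

    def test_k_above_cell_count_rejected(self):
        rng = np.random.default_rng(0)
        _, norm = norm_from_array(rng.integers(1, 5, (10, 4)),
                                  [f"G{i}" for i in range(10)])
        with pytest.raises(ValidationError):
            populations.cluster_cells(norm, list(norm.gene_ids), k=5)

    def test_two_population_recovery(self):
        """Two populations with 8-fold 10-marker programs separate at
        adjusted agreement >= 0.95."""
        fractions = {"WT": {"rod": 0.5, "ML-cone": 0.5},
                     "MUT": {"cod": 0.5, "ML-cone": 0.5}}
        spec = conecod.SyntheticSpec(n_cells_per_genotype=500,
                                     n_genes_total=1500, seed=3,
                                     population_fractions=fractions)
        counts, meta, truth = conecod.generate_organoid_dataset(spec)
        counts_f, norm, ann = run_qc(counts, meta)
        wt = np.flatnonzero(ann["genotype"].to_numpy() == "WT")
        norm_wt = NormMatrix(norm.values[:, wt], norm.gene_ids,
                             norm.barcodes[wt])
        hvg = qc.select_hvg(norm_wt, ann.iloc[wt], n_top=150)
        clusters = populations.cluster_cells(norm_wt, hvg, k=2, seed=0)
        true = truth.population.loc[ann.index[wt]].to_numpy()
        assert adjusted_rand_score(true, clusters) >= 0.95

    def test_identical_cells_degenerate(self):
        arr = np.tile([[2], [3], [1]], (1, 30))
        _, norm = norm_from_array(arr, ["A", "B", "C"])
        clusters = populations.cluster_cells(norm, ["A", "B", "C"], k=2,
                                             seed=0)
        assert len(clusters) == 30  # no crash; labels cover every cell


class TestAnnotateClusters:
    def test_rod_assignment_from_markers(self):
        # cluster 0 high NR2E3/SAG, cluster 1 high ARR3/OPN1MW
        arr = np.zeros((4, 40), dtype=int)
        arr[0, :20] = 8   # NR2E3
        arr[1, :20] = 8   # SAG
        arr[2, 20:] = 8   # ARR3
        arr[3, 20:] = 8   # OPN1MW
        arr += 1  # keep every cell non-empty
        _, norm = norm_from_array(arr, ["NR2E3", "SAG", "ARR3", "OPN1MW"])
        clusters = np.array([0] * 20 + [1] * 20)
        with pytest.warns(UserWarning):  # most panel genes are absent
            res = populations.annotate_clusters(norm, clusters)
        assert res.population[0] == "rod"
        assert res.population[1] == "ML-cone"

    def test_uniform_expression_tie_flagged_ambiguous(self):
        arr = np.ones((3, 20), dtype=int)
        _, norm = norm_from_array(arr, ["NR2E3", "ARR3", "OPN1SW"])
        clusters = np.array([0] * 10 + [1] * 10)
        panel = {"b-pop": ["NR2E3"], "a-pop": ["NR2E3"]}
        res = populations.annotate_clusters(norm, clusters, panel)
        assert res.population[0] == "a-pop"  # name-order tie break
        assert 0 in res.ambiguous and 1 in res.ambiguous

    def test_no_panel_gene_present_is_error(self):
        arr = np.ones((2, 10), dtype=int)
        _, norm = norm_from_array(arr, ["X1", "X2"])
        with pytest.raises(AnnotationError), pytest.warns(UserWarning):
            populations.annotate_clusters(norm, np.zeros(10, dtype=int),
                                          {"rod": ["NR2E3"]})

    def test_six_population_cluster_naming(self):
        """Every cluster of a six-population fixture is named after its
        majority true population."""
        fractions = {
            "WT": {"rod": .2, "ML-cone": .2, "developing": .15,
                   "bipolar": .15, "muller": .15, "amacrine": .15},
            "MUT": {"cod": .2, "ML-cone": .2, "developing": .15,
                    "bipolar": .15, "muller": .15, "amacrine": .15}}
        spec = conecod.SyntheticSpec(n_cells_per_genotype=600,
                                     n_genes_total=1500, seed=5,
                                     population_fractions=fractions)
        counts, meta, truth = conecod.generate_organoid_dataset(spec)
        counts_f, norm, ann = run_qc(counts, meta)
        true = truth.population.loc[ann.index].to_numpy()
        hvg = qc.select_hvg(norm, ann, n_top=200)
        clusters = populations.cluster_cells(norm, hvg, k=8, seed=0)
        res = populations.annotate_clusters(norm, clusters)
        correct = sum(
            pd.Series(true[clusters == cid]).mode()[0] == name
            for cid, name in res.population.items())
        assert correct / len(res.population) >= 0.95

    def test_permutation_invariance(self, organoid_dataset):
        norm = organoid_dataset["norm"]
        rng = np.random.default_rng(0)
        clusters = rng.integers(0, 4, norm.n_cells)
        res = populations.annotate_clusters(norm, clusters)
        perm = rng.permutation(norm.n_cells)
        norm_p = NormMatrix(norm.values[:, perm], norm.gene_ids,
                            norm.barcodes[perm])
        res_p = populations.annotate_clusters(norm_p, clusters[perm])
        assert res.population == res_p.population


class TestExpressionSummary:
    def test_arithmetic_example(self):
        # group of 10 cells, gene nonzero in 3 with normalized values 1,2,3
        raw_vals = np.zeros(10, dtype=int)
        raw_vals[:3] = [1, 2, 3]
        arr = np.vstack([raw_vals, np.full(10, 5)])
        counts, norm = norm_from_array(arr, ["G", "FILL"])
        # overwrite normalized values with the stated ones for exactness
        norm.values = sp.csr_matrix(
            np.vstack([np.where(raw_vals > 0, [1, 2, 3] + [0] * 7, 0.0),
                       norm.values.toarray()[1]]))
        s = populations.expression_summary(counts, norm, "G", np.ones(10, bool))
        assert s.pct_expressing == pytest.approx(30.0)
        assert s.mean_in_expressers == pytest.approx(2.0)
        assert s.mean_total == pytest.approx(0.6)

    def test_absent_gene_gives_zero_triple(self):
        arr = np.vstack([np.zeros(6, dtype=int), np.full(6, 2)])
        counts, norm = norm_from_array(arr, ["G", "FILL"])
        s = populations.expression_summary(counts, norm, "G", np.ones(6, bool))
        assert (s.pct_expressing, s.mean_in_expressers, s.mean_total) == (0, 0, 0)

    def test_empty_group_rejected(self, organoid_dataset):
        with pytest.raises(ValidationError):
            populations.expression_summary(
                organoid_dataset["raw"], organoid_dataset["norm"], "OPN1SW",
                np.zeros(organoid_dataset["raw"].n_cells, bool))

    def test_identity_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        arr = rng.integers(0, 4, size=(30, 50))
        arr[:, arr.sum(axis=0) == 0] += 1
        counts, norm = norm_from_array(arr, [f"G{i}" for i in range(30)])
        mask = rng.random(50) < 0.6
        for gene in counts.gene_ids[:10]:
            s = populations.expression_summary(counts, norm, gene, mask)
            assert s.mean_total == pytest.approx(
                s.mean_in_expressers * s.pct_expressing / 100.0, abs=1e-9)


class TestCompareExpressionGroups:
    def test_identical_groups_p_near_one(self):
        arr = np.tile(np.arange(1, 21), (2, 1))
        counts, norm = norm_from_array(arr, ["G", "FILL"])
        mask = np.zeros(20, bool)
        mask[:10] = True
        # same multiset of values on both sides
        arr2 = np.vstack([np.concatenate([np.arange(1, 11)] * 2),
                          np.full(20, 3)])
        counts, norm = norm_from_array(arr2, ["G", "FILL"])
        res = populations.compare_expression_groups(counts, norm, "G", mask,
                                                    ~mask)
        assert res.p_proportion == pytest.approx(1.0, abs=1e-6)
        assert res.p_level == pytest.approx(1.0, abs=1e-6)

    def test_extreme_proportion_difference(self):
        g = np.concatenate([np.ones(100, int), np.zeros(100, int),
                            np.zeros(200, int)])
        arr = np.vstack([g, np.full(400, 2)])
        counts, norm = norm_from_array(arr, ["G", "FILL"])
        mask_a = np.arange(400) < 200
        res = populations.compare_expression_groups(counts, norm, "G",
                                                    mask_a, ~mask_a)
        assert res.p_proportion < 1e-6

    def test_no_expressers_flagged(self):
        arr = np.vstack([np.zeros(10, int), np.full(10, 2)])
        counts, norm = norm_from_array(arr, ["G", "FILL"])
        mask = np.arange(10) < 5
        res = populations.compare_expression_groups(counts, norm, "G", mask,
                                                    ~mask)
        assert res.p_level == 1.0 and not res.level_defined

    def test_type_one_error_calibration(self):
        """Under the null (one distribution split at random) the level test
        rejects at ~alpha."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_trials = 1000
        for _ in range(n_trials):
            values = rng.poisson(3.0, size=80) + 1  # everyone expresses
            arr = np.vstack([values, np.full(80, 2)])
            counts, norm = norm_from_array(arr, ["G", "FILL"])
            mask = np.zeros(80, bool)
            mask[rng.choice(80, 40, replace=False)] = True
            res = populations.compare_expression_groups(counts, norm, "G",
                                                        mask, ~mask)
            rejections += res.p_level < 0.05
        assert 0.03 <= rejections / n_trials <= 0.07


class TestRefmapSpearman:
    def _profile(self, values, genes):
        return pd.Series(values, index=genes)

    def test_identity_reference_has_rho_one(self):
        query = self._profile([1.0, 2.0, 3.0, 4.0], list("ABCD"))
        refs = [populations.ReferenceProfile("self", query.copy())]
        out = populations.refmap_spearman(query, refs)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(20)]
        query = self._profile(rng.random(20), genes)
        refs = [populations.ReferenceProfile("exp", np.exp(query) - 0.3)]
        out = populations.refmap_spearman(query, refs)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_constructed_best_match_wins(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(50)]
        query = self._profile(np.sort(rng.random(50)), genes)
        agree = query.rank()  # same ranks
        scrambled = self._profile(query.sample(frac=1.0, random_state=2)
                                  .to_numpy(), genes)
        out = populations.refmap_spearman(query, [
            populations.ReferenceProfile("fetal-like", agree),
            populations.ReferenceProfile("scrambled", scrambled)])
        assert out.loc[0, "reference"] == "fetal-like"

    def test_too_few_shared_genes(self):
        query = self._profile([1.0, 2.0], ["A", "B"])
        refs = [populations.ReferenceProfile("tiny", query.copy())]
        with pytest.raises(ValidationError):
            populations.refmap_spearman(query, refs)


class TestDdcq:
    def test_target_equals_housekeeping_gives_fold_one(self):
        rows = []
        for cond in ("WT", "MUT"):
            for s in range(3):
                for gene in ("ACTB", "GAPDH", "NRL"):
                    for rep in range(2):
                        rows.append({"sample": f"{cond}{s}",
                                     "condition": cond, "gene": gene,
                                     "replicate": rep, "cq": 20.0})
        cq = conecod.CqTable(pd.DataFrame(rows))
        res = populations.ddcq_fold_change(cq)
        assert res.loc["NRL", "fold_change"] == pytest.approx(1.0)

    def test_missing_housekeeping_rejected(self):
        rows = [{"sample": "WT1", "condition": "WT", "gene": "ACTB",
                 "replicate": r, "cq": 20.0} for r in range(2)]
        with pytest.raises(ValidationError):
            conecod.CqTable(pd.DataFrame(rows))

    def test_direction_and_significance_pattern(self):
        """Rod transcripts down and S-opsin up in the mutant: signs match
        the construction with Mann-Whitney p below 0.005 at n=6 per arm."""
        folds = {"NRL": 0.1, "NR2E3": 0.15, "GNAT1": 0.2, "OPN1SW": 6.0}
        cq = conecod.generate_qpcr_table(folds, n_reps=3, noise_sd=0.1,
                                         seed=4, n_samples_per_condition=6)
        res = populations.ddcq_fold_change(cq)
        for gene, fold in folds.items():
            assert (res.loc[gene, "log2_fold"] > 0) == (fold > 1)
            assert res.loc[gene, "p_mannwhitney"] < 0.005

    def test_housekeeping_combination_flag(self):
        cq = conecod.generate_qpcr_table({"G": 4.0}, n_reps=3, noise_sd=0.0,
                                         seed=0)
        geo = populations.ddcq_fold_change(cq, housekeeping_combine="geometric")
        ari = populations.ddcq_fold_change(cq,
                                           housekeeping_combine="arithmetic")
        # both cancel in the noise-free double difference
        assert geo.loc["G", "fold_change"] == pytest.approx(4.0)
        assert ari.loc["G", "fold_change"] == pytest.approx(4.0)
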