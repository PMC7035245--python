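import numpy as np
import pandas as pd
import pytest

import conecod
from conecod import qc, trajectory


def run_qc(counts, metadata, min_genes=50, max_mito=1.0):
    """Standard QC + normalization used by most fixtures (small universes
    need a lower gene floor than the 200-gene droplet default)."""
    ann = qc.compute_cell_qc(counts, metadata=metadata)
    cfg = qc.QCConfig(min_genes_per_cell=min_genes, max_mito_fraction=max_mito)
    counts_f, ann = qc.filter_cells(counts, ann, cfg)
    counts_f = qc.filter_genes(counts_f, cfg.min_cells_per_gene)
    return counts_f, qc.normalize(counts_f), ann


@pytest.fixture(scope="session")
def organoid_dataset():
    """Default-composition organoid run (both genotypes, all populations)."""
    spec = conecod.SyntheticSpec(n_cells_per_genotype=1200,
                                 n_genes_total=1000, seed=7)
    counts, metadata, truth = conecod.generate_organoid_dataset(spec)
    counts_f, norm, ann = run_qc(counts, metadata)
    return {"raw": counts_f, "norm": norm, "ann": ann, "truth": truth}


@pytest.fixture(scope="session")
def bifurcation_dataset():
    """Stock bifurcating maturation run with true pseudotime/branch."""
    spec = conecod.SyntheticSpec(seed=11)
    counts, metadata, truth = conecod.generate_bifurcation(spec,
                                                           branch_point=0.45)
    counts_f, norm, ann = run_qc(counts, metadata, min_genes=200,
                                 max_mito=0.20)
    labels = pd.DataFrame(
        {"age_day": 170,
         "coarse_type": trajectory.coarse_type_labels(counts_f).to_numpy()},
        index=ann.index)
    return {"raw": counts_f, "norm": norm, "ann": ann, "truth": truth,
            "labels": labels}


def branch_accuracy(pred_branches, true_branches):
    """Best trunk-preserving mapping of branch-1/2 onto rod/cone fates."""
    true_branches = np.asarray(true_branches)
    best = 0.0
    for mapping in ({"branch-1": "rod-branch", "branch-2": "cone-branch"},
                    {"branch-1": "cone-branch", "branch-2": "rod-branch"}):
        mapped = np.array([mapping.get(b, "trunk") for b in pred_branches])
        best = max(best, float((mapped == true_branches).mean()))
    return best
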