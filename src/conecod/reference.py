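"""Published reference values for optional external-data checks.

These numbers describe the deposited GSE143669 retinal-organoid dataset
(day-170 Drop-seq run, wild-type vs NRL-null L75Pfs genotypes).
Reproducing them requires downloading the deposited matrices and re-running
QC; they are recorded here so a run on the real data can be checked against
the published analysis, and so tests can verify that our expression-group
statistics satisfy the same internal identities the published table does.
"""

# Day-170 expression-group statistics for the three diagnostic markers:
# (percent of cells expressing, mean normalized expression within
# expressers, mean total normalized expression), per genotype.
TABLE1_D170 = {
    "OPN1SW": {"WT": (0.796, 3.648, 0.029), "MUT": (8.021, 3.793, 0.304)},
    "OPN1MW": {"WT": (3.711, 2.612, 0.097), "MUT": (2.278, 2.654, 0.060)},
    "NR2E3": {"WT": (7.735, 3.084, 0.239), "MUT": (0.667, 2.657, 0.018)},
}

# Single-cell transcriptome totals in the deposited day-170 run.
CELL_TOTALS_D170 = {"WT": 8920, "MUT": 15447}

# Bonferroni denominators: genes expressed at each timepoint.
GENES_EXPRESSED = {"d100": 23645, "d170": 25622}

# Binding-site enrichment configuration (counts printed for the deposited
# photoreceptor dataset): 475 target genes, 375 of them among the 14,657
# genes expressed in >= 10 cells (out of 28,040 annotated human genes),
# and 34 among the 791 genes differentially expressed between mutant
# rod-like cells and WT cones.
ENRICHMENT_COUNTS = {
    "n_human_genes": 28040,
    "n_expressed_genes": 14657,
    "n_de_genes": 791,
    "target_set_size": 475,
    "target_in_expressed": 375,
    "target_in_de": 34,
}
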