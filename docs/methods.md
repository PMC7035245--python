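# Methods

## Scope and data model

`conecod` analyses genes × cells UMI count matrices from retinal organoid
single-cell RNA-seq, stratified by genotype (wild-type vs NRL-null).
Counts live in a sparse `CountMatrix`; log-normalized expression in a
`NormMatrix` (`e = ln(1 + s·x/T)`, `s = 10,000`, `T` the cell's total
UMIs); per-cell covariates and derived QC statistics travel in a pandas
DataFrame indexed by barcode. Zero counts map to zero normalized
expression exactly, and normalization is invariant to per-cell count
scaling.

The normalization formula itself is a convention choice: counts-per-10k
with a natural log1p. The natural log matters downstream because the
differential-expression filter is stated on the natural-log fold-change
scale (0.5 ≈ 1.65-fold).

## Quality control

Cells are kept when they express at least `min_genes_per_cell` genes
(default 200) and their mitochondrial UMI fraction (genes prefixed `MT-`)
is at most `max_mito_fraction` (default 0.20 for late-stage runs; 0.15 is
the convention for day-100-like runs). Genes are kept when detected in at
least `min_cells_per_gene` cells (default 2). The two filters are
idempotent in sequence. QC is applied per age-group dataset with its own
mitochondrial ceiling.

## Highly variable genes

Per genotype, genes are ranked by dispersion — variance/mean of the
*de-logged* normalized expression (i.e. counts per 10k) — z-scored within
20 equal-frequency mean bins; the union of each genotype's top `n_top`
(default 2000) is returned. Two deliberate details:

* The dispersion is computed on the de-logged scale. On the log scale the
  variance-to-mean ratio of a strongly bimodal marker is numerically
  indistinguishable from shot noise, and spike-in recovery fails; on the
  counts scale an 8-fold bimodal gene has a dispersion far above its
  mean-matched neighbours.
* Mitochondrial genes are excluded by default. Their apparent dispersion
  tracks the per-cell mitochondrial-content covariate rather than cell
  identity, and because they are among the highest-mean genes they
  dominate the top bin's z statistics and crowd out real markers.

Ties break lexicographically by gene id, so selection is deterministic.

## Partitioning and annotation

Cells are partitioned by PCA (on z-scaled variable-gene expression,
clipped at ±10) followed by k-means with a fixed seed. This replaces the
cross-genotype canonical-correlation alignment used in the original
analysis: the synthetic generator produces no batch effect between
genotypes, reproduction of real-data cluster geometry is not a goal here,
and externally computed labels can be supplied to bypass clustering.

A cluster's population is the marker panel with the highest score, where
the score is the mean over panel markers of the cluster-average expression
z-scored against the gene's across-cell mean and standard deviation.
Z-scoring against cell-level statistics (rather than across cluster means)
keeps scores meaningful with any number of clusters — across-cluster
z-scores degenerate to ±1 at k = 2. Ties break by panel name order and
are flagged ambiguous. Default panels use retinal marker genes named in
the literature (NR2E3/SAG/GNAT1… for rods; OPN1MW/ARR3/PDE6H… for
ML-cones; OPN1SW/CNGB3 for S-cones; OPN1SW+GNGT1 for cods; CRX/RCVRN for
developing photoreceptors; VSX1/VSX2/CABP5 for bipolar cells; …) and are
fully user-overridable via YAML.

Reference mapping is a Spearman correlation of a population's mean
expression profile against each reference profile over the shared-gene
intersection (≥ 3 genes), invariant to monotone transforms of either side.

## Expression-group statistics

For a gene and a cell group: `pct_expressing` = share of cells with raw
count above a threshold (default 0); `mean_in_expressers` = mean
normalized expression over those cells; `mean_total` = mean over all group
cells. By construction `mean_total = mean_in_expressers ·
pct_expressing/100`, an identity the published day-170 marker table also
satisfies (those published values, and the deposited dataset's cell
totals, are recorded in `conecod.reference`; they can only be recomputed
from the deposited matrices themselves). Group differences get two
separate calls: a two-sided two-proportion z test on expressing counts
(Fisher's exact test when any expected cell count is below 5) and a
two-sided Wilcoxon rank-sum on normalized expression within expressers;
with no expressers on either side the level test is undefined and is
reported as 1 with a flag.

## Differential expression

Per gene, a two-sided Wilcoxon rank-sum on normalized expression between
the two cell groups — exact null enumeration when the pooled sample size
is ≤ 12 with no ties, otherwise the normal approximation with tie and
continuity corrections. The normal approximation is accurate to a few
percent for moderate p but, like any normal tail approximation, its
*relative* error grows without bound in the far tail; the test suite
asserts ≤ 5% relative error for p ≥ 0.05 and ≤ 0.02 absolute error
everywhere at n = 6 + 6.

The natural-log fold change de-logs each group's values, averages, and
re-logs with a pseudocount: `ln(mean(e^a − 1) + 1) − ln(mean(e^b − 1) + 1)`.
This form reproduces the "ln FC 0.5 ≈ 1.6-fold" equivalence; a plain
difference-of-mean-logs variant sits behind `method="mean-log"`.

Bonferroni correction multiplies raw p by the number of genes expressed at
the timepoint (the gene count of the already-filtered matrix by default,
or an explicit integer). A gene is significant when `p_bonf < 0.05` and
`|ln FC| > 0.5`. The tested universe is restricted to genes detected in at
least `de_universe_min_cells` (default 10) of the compared cells.

The three-way framework runs query-vs-refA and query-vs-refB and
classifies each gene: not significant vs one reference ⇒ at that
reference's level; significant vs both with opposite fold signs ⇒
intermediate; same sign ⇒ above/below both; significant vs neither ⇒ ns.
With refA = WT rods and refB = WT cones, the cod signature reads as cone
genes at rod level, rod genes at cone level, and *OPN1SW* above both.

## Gene-set enrichment

Given a universe of N genes, a target set S, and a selection of k genes,
the observed statistic is |S ∩ selection|/|S| — the full set size is the
denominator, matching the printed 7.2% = 34/475 and 80% = 375/475
conventions. The null draws k genes uniformly without replacement,
`n_iterations` = 1000 times. Reported inference:

* `p_t`: two-tailed one-sample t of the null fractions against the
  observed value (n−1 df) — the test described for the original analysis;
* `p_empirical`: add-one tail estimator, doubled and capped at 1 (never
  exactly 0);
* `p_hypergeom`: exact upper tail P(X ≥ observed), the statistically
  preferable quantity, always co-reported.

The closed-form expectation is |S∩U|·k/(N·|S|). For the expressed-gene
configuration (draw 14,657 of 28,040) this gives 52.27%, which the
original text rounds to "the expected 50%"; the package reports the
computed value. For the DE-gene configuration (draw 791 of 14,657 with
375 target members) it gives 4.26%, printed as 4.2%.

`ora` generalizes to many gene sets against a query/background pair with
exact hypergeometric p and Benjamini–Hochberg adjustment.

## Pseudotime

**Ordering genes.** A semi-supervised negative-binomial likelihood-ratio
test per gene: a log-linear NB model with a group indicator for the
age × coarse-type combination (NR2E3 detected ⇒ rod, else ARR3 detected ⇒
cone, neither ⇒ undifferentiated) and a log-total-count offset, against
the offset-only null. The per-gene dispersion (variance = μ + φμ²) is
estimated once by method of moments under the null (floor 1e−8) and held
fixed in both models, making the statistic a clean χ² likelihood ratio;
the group-mean MLEs come from a vectorized Newton solve of the concave
1-parameter problem, cross-checked in the tests against grid-maximized
likelihoods. Genes are ranked by p, ribosomal (RPL*/RPS*) and
mitochondrial (MT-*) genes are dropped, and the top `n_ordering_genes`
(default 780, the published convention for a ~25k-gene matrix; scale it
with the universe — tests on a 2,000-gene synthetic universe use ~60) are
returned.

**Trajectory.** PCA on z-scaled ordering-gene expression to
`n_components` = 4 — a bifurcating lineage is intrinsically
low-dimensional, and additional components only add isotropic noise that
distorts centroid distances. Each cell's embedding is then denoised by
averaging with its 50 nearest neighbours; k-means (default 12 centroids,
30 restarts) and a minimum spanning tree over centroid Euclidean distances
give the backbone. The root is the tree *endpoint* (a lineage origin is
never an interior node) with the lowest maturity score — mean expression
of opsin/rod markers minus mean expression of retinal progenitor genes,
so equally opsin-negative candidates are separated by progenitor content.
Each cell is projected onto its nearest tree edge; pseudotime is the
root-geodesic arc length at the projection (projections may run past the
root and leaf centroids so end segments keep their within-segment
ordering), shifted to a minimum of 0. States are the maximal tree
segments delimited by degree ≥ 3 nodes. Branch labels are anchored on the
two dominant fates: the two leaves farthest from the root with divergent
root paths define the branch node where those paths split; centroids
beyond it toward either fate are branch-1/branch-2, everything else —
including short noise twigs — stays trunk. Each of these choices fixes a
concrete failure mode observed across simulation replicates (interior
roots fold the trunk; per-centroid labels misassign boundary cells;
first-degree-3 branch detection fires on noise twigs).

**Branch differential expression** reuses the NB likelihood-ratio test
with the branch as the group indicator, Benjamini–Hochberg q-values, and
a top-N (default 100) non-ribosomal gene set for heatmap export.

## qPCR relative quantification

Per sample, ΔC(q) of a target is its mean Cq minus the geometric mean of
the two housekeeping genes' mean Cq values ("geometric mean of two
housekeeping genes" read at the Cq level; the arithmetic-mean-of-Cq
variant — equivalent to a geometric mean of linear abundances — is
available behind a flag; the choice cancels exactly in the double
difference for balanced designs). ΔΔC(q) subtracts the mean
reference-condition ΔC(q); fold change is `2^−mean(ΔΔCq)` over test
samples; p-values compare per-sample ΔC(q) between conditions with a
two-sided Mann–Whitney test.

## Synthetic data generator

The generator emulates a Drop-seq organoid run, not any particular real
dataset. Counts are negative binomial with variance μ + φμ² (φ = 0.3 by
default; φ = 0 falls back to Poisson). Its structure, with defaults chosen
once as field-realistic study conditions:

* 5,000 cells per genotype over a 2,000-gene universe at ~1,000 UMI per
  cell; composition is genotype-specific with rods only in WT and cods
  only in the mutant (validated);
* per-gene baseline means get a mean-preserving log-normal spread
  (σ = 1): real transcriptome means span orders of magnitude, and a flat
  baseline makes binned-dispersion HVG selection degenerate (all markers
  land in one bin and cancel);
* marker genes are *specific*: off-state `baseline_mean ·
  marker_off_scale` (0.25) outside their population, `baseline_mean ·
  fold` (fold 8 for primary markers) inside — cell-type markers in real
  data are near-absent elsewhere, not merely lower;
* per-cell depth factors are log-normal (σ = 0.35) and a Beta(2, 18)
  mitochondrial fraction of each cell's expected depth is reallocated to
  the 13 MT- genes, so the 15%/20% QC ceilings are exercised;
* the bifurcation variant places cells uniformly on a [0, 1] maturation
  axis that splits at `branch_point` into rod and cone fates; progenitor
  genes decay with pseudotime, pan-photoreceptor maturation genes rise on
  every path, and branch programs activate switch-like at commitment (30%
  basal activation, then a linear ramp) — fate commitment in vivo is a
  transcriptional switch, and maturation involves many more genes than
  fate choice;
* an optional doublet rate merges random cell pairs; ambient RNA, batch
  chemistry, and read-level structure are not modeled.

Consequences for interpretation: passing recovery tests shows the pipeline
recovers planted structure under NB noise with depth/mito covariates; it
does not certify performance under batch effects, ambient contamination,
or real biological manifolds, none of which are simulated. Fixing the
seed reproduces every matrix bit for bit.

## Pipeline

`conecod run` executes simulate/ingest → QC → HVG → cluster → annotate →
expression summary → per-population genotype DE → cod tri-classification
(mutant cod cells vs WT rods and WT cones) → binding-site enrichment of
the non-ns tri-classified genes → WT-photoreceptor trajectory, writing
every intermediate as MTX/TSV/JSON and a machine-readable report. A
single seed fans out to per-stage seeds through `numpy.random.SeedSequence`,
so identical config + seed gives identical reports (wall time aside).

## Problem sizes used in the tests

Unit and recovery tests run on scaled-down instances chosen to keep the
statistical claims meaningful: 2-population annotation fixtures at 500
cells per genotype over 1,500 genes; the full-composition fixture at
1,200 cells per genotype over 1,000 genes; the bifurcation recovery at the
generator's stock 5,000 cells over 2,000 genes with 60 ordering genes
(the 780-gene published convention scaled to the universe); DE
calibration over 20 seeds of 2,000-gene null matrices; Monte-Carlo oracle
sweeps over 50 random configurations at 1,000 iterations. The enrichment
acceptance computation runs at the full published sizes (N = 14,657,
k = 791, 1000 iterations) — it is cheap.

## Known limitations

* The clustering stage is k-means on PCA: no graph-based community
  detection, no batch integration. Supply external labels for integrated
  real datasets.
* The trajectory is a centroid MST — adequate for one bifurcation, not
  for complex multi-branch topologies; the state count is an emergent
  property, not a calibrated quantity.
* The NB tests use moment-estimated, fixed dispersions; no per-group
  dispersion or shrinkage across genes.
* ΔΔC(q) assumes amplification efficiency 2 for all assays.
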