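"""Synthetic Drop-seq-like organoid data with known ground truth.

Emulates the structure of NRL-null (mutant) versus wild-type retinal
organoid single-cell UMI data: distinct retinal populations driven by
marker-gene programs, genotype-specific composition (rods only in WT, the
rod/cone-intermediate "cod" population only in the mutant), per-cell
sequencing-depth and mitochondrial-content covariates, and — via
:func:`generate_bifurcation` — a maturation axis that splits into rod and
cone fates.  Counts follow a negative binomial with variance
``mu + phi * mu**2``, the standard over-dispersed model for UMI data.

Everything is driven by a single integer seed, so a fixed
:class:`SyntheticSpec` reproduces its output bit for bit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .containers import CountMatrix, ValidationError, write_counts

WT = "WT"
MUT = "MUT"

# Marker programs use real human retinal gene symbols so that the default
# marker panels apply unchanged to real count matrices.
DEFAULT_MARKER_PROGRAM: dict[str, list[tuple[str, float]]] = {
    "rod": [("NR2E3", 8.0), ("SAG", 8.0), ("GNAT1", 8.0), ("NRL", 8.0),
            ("ROM1", 8.0), ("CNGB1", 8.0), ("PDE6G", 8.0), ("GNB1", 8.0),
            ("SAMD7", 8.0), ("GNGT1", 8.0)],
    "ML-cone": [("OPN1MW", 8.0), ("ARR3", 8.0), ("PDE6H", 8.0), ("GNAT2", 8.0),
                ("GNB3", 8.0), ("GNGT2", 8.0), ("PDE6C", 8.0), ("GUCA1C", 8.0),
                ("MYL4", 8.0), ("MEF2C", 8.0)],
    "S-cone": [("OPN1SW", 8.0), ("ARR3", 6.0), ("PDE6H", 6.0), ("GNAT2", 6.0),
               ("CNGB3", 8.0), ("MEF2C", 6.0), ("GNB3", 6.0), ("CCDC136", 8.0)],
    # cods: high S-opsin plus the rod transducin GNGT1; rod and cone
    # program genes stay at their off-state — which is exactly "rod genes
    # at cone levels and cone genes at rod levels"
    "cod": [("OPN1SW", 8.0), ("GNGT1", 3.0)],
    "developing": [("CRX", 8.0), ("RCVRN", 8.0), ("OTX2", 8.0), ("NEUROD1", 8.0),
                   ("PRDM1", 8.0), ("AIPL1", 8.0), ("RAX2", 8.0), ("CRABP2", 8.0)],
    "bipolar": [("VSX1", 8.0), ("VSX2", 8.0), ("CABP5", 8.0), ("GRM6", 8.0),
                ("PRKCA", 8.0), ("TRPM1", 8.0), ("GRIK1", 8.0), ("ISL1", 8.0)],
    "amacrine": [("TFAP2A", 8.0), ("GAD1", 8.0), ("SLC32A1", 8.0), ("CALB2", 8.0),
                 ("GAD2", 8.0), ("SLC6A9", 8.0), ("CHAT", 8.0), ("TH", 8.0)],
    "horizontal": [("ONECUT1", 8.0), ("ONECUT2", 8.0), ("LHX1", 8.0),
                   ("CALB1", 8.0), ("NDNF", 8.0), ("TPBG", 8.0)],
    "muller": [("RLBP1", 8.0), ("SLC1A3", 8.0), ("GLUL", 8.0), ("APOE", 8.0),
               ("CLU", 8.0), ("AQP4", 8.0), ("SOX9", 8.0), ("CRYM", 8.0)],
    "RGC": [("RBPMS", 8.0), ("POU4F2", 8.0), ("SNCG", 8.0), ("NEFL", 8.0),
            ("GAP43", 8.0), ("THY1", 8.0)],
}

DEFAULT_POPULATION_FRACTIONS: dict[str, dict[str, float]] = {
    WT: {"rod": 0.30, "ML-cone": 0.12, "S-cone": 0.03, "developing": 0.25,
         "bipolar": 0.10, "amacrine": 0.07, "horizontal": 0.05, "muller": 0.06,
         "RGC": 0.02},
    MUT: {"cod": 0.25, "ML-cone": 0.08, "S-cone": 0.12, "developing": 0.25,
          "bipolar": 0.10, "amacrine": 0.08, "horizontal": 0.05, "muller": 0.05,
          "RGC": 0.02},
}

MITO_GENES = ["MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6",
              "MT-CO3", "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6",
              "MT-CYB"]
RIBO_GENES = [f"RPL{i}" for i in range(1, 16)] + [f"RPS{i}" for i in range(1, 16)]

# progenitor program that decays along pseudotime in the bifurcation
# generator; maturation genes ramp up in every photoreceptor regardless of
# fate.  Maturation involves many more genes than fate choice, which is why
# trajectory orderings are dominated by age-varying genes.
PROGENITOR_GENES = ["NES", "SOX2", "PAX6", "LHX2", "HES1", "ASCL1", "SFRP2",
                    "FGF19", "MKI67", "CCND1", "SOX4", "SOX11", "HES6", "DLL3"]
PAN_MATURATION_GENES = ["RBP3", "THRB", "RXRG", "SIX6", "ELOVL2", "IMPG1",
                        "IMPG2", "PRPH2", "RP1", "CRB1"]


@dataclass
class SyntheticSpec:
    """Parameters of the organoid-like count simulator.

    Defaults emulate a late-stage Drop-seq run: 5,000 cells per genotype,
    2,000-gene universe, ~0.5 mean UMI per gene per cell (≈1,000 UMI/cell)
    with mean-preserving log-normal spread across genes (sigma 1, so gene
    means span orders of magnitude as in real transcriptomes),
    negative-binomial dispersion 0.3, marker genes at a low off-state
    (``baseline_mean * marker_off_scale``) outside their population and
    ``baseline_mean * fold`` inside it (cell-type markers are specific, not
    merely elevated), log-normal depth spread (sigma 0.35)
    and Beta(2, 18) mitochondrial fractions (mean 10%, with a tail beyond
    the 15%/20% QC ceilings).
    """

    n_cells_per_genotype: int = 5000
    population_fractions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in
                                 DEFAULT_POPULATION_FRACTIONS.items()})
    marker_program: dict[str, list[tuple[str, float]]] = field(
        default_factory=lambda: {p: list(v) for p, v in
                                 DEFAULT_MARKER_PROGRAM.items()})
    baseline_mean: float = 0.5
    marker_off_scale: float = 0.25
    gene_mean_lognormal_sigma: float = 1.0
    nb_dispersion: float = 0.3
    depth_lognormal_mu_sigma: tuple[float, float] = (0.0, 0.35)
    mito_beta_params: tuple[float, float] = (2.0, 18.0)
    n_genes_total: int = 2000
    seed: int = 0
    age_day: int = 170
    organoids_per_genotype: int = 4
    doublet_rate: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_cells_per_genotype < 0:
            raise ValidationError("n_cells_per_genotype must be >= 0")
        if self.baseline_mean <= 0 or self.nb_dispersion < 0:
            raise ValidationError("baseline_mean > 0 and nb_dispersion >= 0 required")
        for genotype, fracs in self.population_fractions.items():
            total = sum(fracs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"population fractions for {genotype} sum to {total}, not 1")
            if any(f < 0 for f in fracs.values()):
                raise ValidationError("population fractions must be >= 0")
        # genotype-specific composition: rods never in the NRL-null mutant,
        # cods never in WT (custom fixtures may omit either population)
        mut = {p for p, f in self.population_fractions.get(MUT, {}).items() if f > 0}
        wt = {p for p, f in self.population_fractions.get(WT, {}).items() if f > 0}
        if "rod" in mut:
            raise ValidationError("mutant composition must exclude 'rod'")
        if "cod" in wt:
            raise ValidationError("WT composition must exclude 'cod'")
        marker_genes = {g for prog in self.marker_program.values() for g, _ in prog}
        if self.n_genes_total < len(marker_genes):
            raise ValidationError(
                "n_genes_total smaller than the number of distinct marker genes")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "marker_program" in raw:
            raw["marker_program"] = {
                p: [(g, float(f)) for g, f in prog]
                for p, prog in raw["marker_program"].items()}
        for key in ("depth_lognormal_mu_sigma", "mito_beta_params"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Per-cell truth emitted alongside every synthetic dataset."""

    population: pd.Series                    # barcode -> true population
    universe: list[str]                      # full gene universe
    binding_site_set: list[str]              # designated TF-target gene set
    pseudotime: pd.Series | None = None      # in [0, 1]; bifurcation runs only
    branch: pd.Series | None = None          # trunk / rod-branch / cone-branch

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"population": self.population})
        if self.pseudotime is not None:
            df["pseudotime"] = self.pseudotime
        if self.branch is not None:
            df["branch"] = self.branch
        return df


def _build_universe(spec: SyntheticSpec) -> list[str]:
    marker_genes: list[str] = []
    for prog in spec.marker_program.values():
        for g, _ in prog:
            if g not in marker_genes:
                marker_genes.append(g)
    fixed = list(dict.fromkeys(marker_genes + PROGENITOR_GENES
                               + PAN_MATURATION_GENES + MITO_GENES
                               + RIBO_GENES))
    n_fill = spec.n_genes_total - len(fixed)
    if n_fill < 0:
        # tiny universes: keep markers, then mito, drop the rest as needed
        fixed = list(dict.fromkeys(marker_genes + MITO_GENES))[: spec.n_genes_total]
        n_fill = spec.n_genes_total - len(fixed)
    fillers = [f"GENE{i:05d}" for i in range(n_fill)]
    return fixed + fillers


def _binding_site_set(universe: list[str], spec: SyntheticSpec,
                      size: int = 100) -> list[str]:
    """Deterministic designated target set: cone-program genes plus fillers."""
    cone = [g for p in ("ML-cone", "S-cone") for g, _ in
            spec.marker_program.get(p, [])]
    members = list(dict.fromkeys(g for g in cone if g in universe))
    for g in universe:
        if len(members) >= size:
            break
        if g.startswith("GENE") and g not in members:
            members.append(g)
    return members


def _gene_baselines(rng: np.random.Generator, spec: SyntheticSpec,
                    universe: list[str],
                    program_genes: set[str]) -> np.ndarray:
    """Per-gene baseline means.

    Non-program genes get a mean-preserving log-normal spread around
    ``baseline_mean`` (real gene means span orders of magnitude); program
    (marker/trajectory) genes get the deterministic off-state
    ``baseline_mean * marker_off_scale``.
    """
    sigma = spec.gene_mean_lognormal_sigma
    if sigma <= 0:
        base = np.full(len(universe), spec.baseline_mean)
    else:
        base = spec.baseline_mean * rng.lognormal(-sigma**2 / 2.0, sigma,
                                                  len(universe))
    off = spec.baseline_mean * spec.marker_off_scale
    for i, g in enumerate(universe):
        if g in program_genes:
            base[i] = off
    return base


def _population_counts(fracs: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment so counts sum exactly to n."""
    names = sorted(fracs)
    raw = {p: fracs[p] * n for p in names}
    counts = {p: int(np.floor(raw[p])) for p in names}
    remainder = n - sum(counts.values())
    order = sorted(names, key=lambda p: (-(raw[p] - counts[p]), p))
    for p in order[:remainder]:
        counts[p] += 1
    return counts


def _nb_sample(rng: np.random.Generator, mu: np.ndarray,
               phi: float) -> np.ndarray:
    """Negative binomial with var = mu + phi mu^2 (Poisson when phi == 0)."""
    if phi <= 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _sample_block(rng: np.random.Generator, base_mean: np.ndarray,
                  depth: np.ndarray, mito_frac: np.ndarray,
                  mito_rows: np.ndarray, phi: float) -> np.ndarray:
    """Counts for a homogeneous cell block.

    ``base_mean`` is the per-gene expected count at unit depth; each cell's
    non-mitochondrial means scale with its depth factor, and MT- genes are
    then allocated the cell's drawn mitochondrial share of total depth.
    """
    non_mito = ~mito_rows
    mu = np.outer(base_mean, depth)  # genes x cells
    if mito_rows.any():
        s_non = base_mean[non_mito].sum() * depth          # per-cell non-MT sum
        total = s_non / np.maximum(1.0 - mito_frac, 1e-6)  # implied cell total
        mu[mito_rows, :] = (mito_frac * total) / mito_rows.sum()
    return _nb_sample(rng, mu, phi)


def generate_organoid_dataset(
        spec: SyntheticSpec,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Simulate WT + mutant organoid UMI matrices with known populations.

    Returns the combined count matrix (genes x cells), a per-cell metadata
    frame (genotype, age, organoid id) and the :class:`GroundTruth`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    universe = _build_universe(spec)
    gene_index = {g: i for i, g in enumerate(universe)}
    for prog in spec.marker_program.values():
        for g, _ in prog:
            if g not in gene_index:
                raise ValidationError(f"marker gene {g} not in gene universe")
    mito_rows = np.array([g.startswith("MT-") for g in universe])
    program_genes = {g for prog in spec.marker_program.values() for g, _ in prog}
    gene_base = _gene_baselines(rng, spec, universe, program_genes)

    blocks: list[sp.csr_matrix] = []
    barcodes: list[str] = []
    meta_rows: list[dict] = []
    truth_pop: list[str] = []
    mu_d, sigma_d = spec.depth_lognormal_mu_sigma
    a_m, b_m = spec.mito_beta_params

    for genotype in sorted(spec.population_fractions):
        fracs = spec.population_fractions[genotype]
        counts_per_pop = _population_counts(fracs, spec.n_cells_per_genotype)
        cell_no = 0
        for pop in sorted(counts_per_pop):
            n_pop = counts_per_pop[pop]
            if n_pop == 0:
                continue
            base = gene_base.copy()
            for g, fold in spec.marker_program.get(pop, []):
                base[gene_index[g]] = spec.baseline_mean * fold
            depth = rng.lognormal(mu_d, sigma_d, size=n_pop)
            mito = rng.beta(a_m, b_m, size=n_pop)
            block = _sample_block(rng, base, depth, mito, mito_rows,
                                  spec.nb_dispersion)
            blocks.append(sp.csr_matrix(block.astype(np.int64)))
            for _ in range(n_pop):
                bc = f"{genotype}_{cell_no:05d}"
                barcodes.append(bc)
                meta_rows.append({
                    "barcode": bc, "genotype": genotype,
                    "age_day": spec.age_day,
                    "organoid_id": f"{genotype}-org{cell_no % spec.organoids_per_genotype + 1}",
                })
                truth_pop.append(pop)
                cell_no += 1

    if blocks:
        values = sp.hstack(blocks, format="csr")
    else:
        values = sp.csr_matrix((len(universe), 0), dtype=np.int64)

    if spec.doublet_rate > 0 and values.shape[1] >= 2:
        values = _inject_doublets(rng, values, spec.doublet_rate)

    counts = CountMatrix(values, np.asarray(universe, dtype=object),
                         np.asarray(barcodes, dtype=object))
    metadata = pd.DataFrame(meta_rows).set_index("barcode") if meta_rows else \
        pd.DataFrame(columns=["genotype", "age_day", "organoid_id"])
    truth = GroundTruth(
        population=pd.Series(truth_pop, index=metadata.index, name="population"),
        universe=universe,
        binding_site_set=_binding_site_set(universe, spec),
    )
    return counts, metadata, truth


def _inject_doublets(rng: np.random.Generator, values: sp.csr_matrix,
                     rate: float) -> sp.csr_matrix:
    """Overwrite a random subset of cells with the sum of two random cells."""
    n = values.shape[1]
    n_doublets = int(round(rate * n))
    if n_doublets == 0:
        return values
    dense = values.tocsc()
    targets = rng.choice(n, size=n_doublets, replace=False)
    lil = dense.tolil()
    for t in targets:
        a, b = rng.choice(n, size=2, replace=False)
        lil[:, t] = (dense[:, a] + dense[:, b])
    return lil.tocsr()


def generate_bifurcation(
        spec: SyntheticSpec, branch_point: float = 0.45,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Simulate a maturation trajectory that bifurcates into rod/cone fates.

    Cells sit uniformly on a pseudotime axis in [0, 1].  Before
    ``branch_point`` every cell is on the trunk; after it, cells commit to
    the rod or cone branch with equal probability.  Progenitor genes decay
    linearly with pseudotime, pan-photoreceptor genes rise along the trunk
    and both branches, and rod/cone programs ramp linearly only after the
    split on their own branch.  The ground truth records true pseudotime
    and branch per cell.
    """
    if not 0.0 < branch_point < 1.0:
        raise ValidationError("branch_point must lie strictly inside (0, 1)")
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    universe = _build_universe(spec)
    gene_index = {g: i for i, g in enumerate(universe)}
    mito_rows = np.array([g.startswith("MT-") for g in universe])
    traj_programs = {g for prog in (spec.marker_program.get("rod", []),
                                    spec.marker_program.get("ML-cone", []),
                                    spec.marker_program.get("developing", []))
                     for g, _ in prog}
    traj_programs |= set(PROGENITOR_GENES) | set(PAN_MATURATION_GENES)
    gene_base = _gene_baselines(rng, spec, universe, set())
    for g in traj_programs:
        if g in gene_index:
            gene_base[gene_index[g]] = spec.baseline_mean

    n = spec.n_cells_per_genotype
    t = np.sort(rng.uniform(0.0, 1.0, size=n))
    branch = np.where(t < branch_point, "trunk",
                      np.where(rng.random(n) < 0.5, "rod-branch", "cone-branch"))

    rod_prog = spec.marker_program.get("rod", [])
    cone_prog = spec.marker_program.get("ML-cone", [])
    devel_prog = spec.marker_program.get("developing", [])

    mu = np.repeat(gene_base[:, None], n, axis=1)
    ramp = np.clip((t - branch_point) / (1.0 - branch_point), 0.0, 1.0)
    for g in PROGENITOR_GENES:
        if g in gene_index:
            mu[gene_index[g]] = gene_base[gene_index[g]] * (1 + 7.0 * (1 - t))
    for g, fold in devel_prog:
        mu[gene_index[g]] = gene_base[gene_index[g]] * (1 + (fold - 1) * t)
    for g in PAN_MATURATION_GENES:
        if g in gene_index:
            mu[gene_index[g]] = gene_base[gene_index[g]] * (1 + 7.0 * t)
    # fate commitment is switch-like: committed cells start their branch
    # program at a basal activation (30% of full) and ramp up from there;
    # a gene carried by both programs keeps the larger elevation
    activation = np.where(ramp > 0, 0.3 + 0.7 * ramp, 0.0)
    for prog, name in ((rod_prog, "rod-branch"), (cone_prog, "cone-branch")):
        on = (branch == name).astype(float)
        for g, fold in prog:
            gi = gene_index[g]
            elevated = gene_base[gi] * (1 + (fold - 1) * activation * on)
            mu[gi] = np.maximum(mu[gi], elevated)

    mu_d, sigma_d = spec.depth_lognormal_mu_sigma
    a_m, b_m = spec.mito_beta_params
    depth = rng.lognormal(mu_d, sigma_d, size=n)
    mito = rng.beta(a_m, b_m, size=n)
    mu *= depth  # broadcast per cell
    if mito_rows.any():
        s_non = mu[~mito_rows].sum(axis=0)
        total = s_non / np.maximum(1.0 - mito, 1e-6)
        mu[mito_rows, :] = (mito * total) / mito_rows.sum()
    values = sp.csr_matrix(_nb_sample(rng, mu, spec.nb_dispersion).astype(np.int64))

    barcodes = np.asarray([f"WT_{i:05d}" for i in range(n)], dtype=object)
    metadata = pd.DataFrame(
        {"genotype": WT, "age_day": spec.age_day,
         "organoid_id": [f"WT-org{i % spec.organoids_per_genotype + 1}"
                         for i in range(n)]},
        index=pd.Index(barcodes, name="barcode"))
    counts = CountMatrix(values, np.asarray(universe, dtype=object), barcodes)
    pop = np.where(branch == "trunk", "developing",
                   np.where(branch == "rod-branch", "rod", "ML-cone"))
    truth = GroundTruth(
        population=pd.Series(pop, index=metadata.index, name="population"),
        universe=universe,
        binding_site_set=_binding_site_set(universe, spec),
        pseudotime=pd.Series(t, index=metadata.index, name="pseudotime"),
        branch=pd.Series(branch, index=metadata.index, name="branch"),
    )
    return counts, metadata, truth


# ---------------------------------------------------------------------------
# qPCR table generator
# ---------------------------------------------------------------------------

DEFAULT_HOUSEKEEPING = ("ACTB", "GAPDH")


@dataclass
class CqTable:
    """Tidy qPCR quantification-cycle table.

    ``data`` has columns sample, condition (WT/MUT), gene, replicate, cq;
    ``housekeeping`` names the two reference genes used for ΔC(q).
    """

    data: pd.DataFrame
    housekeeping: tuple[str, str] = DEFAULT_HOUSEKEEPING

    def __post_init__(self) -> None:
        required = {"sample", "condition", "gene", "cq"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"CqTable missing columns: {sorted(missing)}")
        per = self.data.groupby(["sample", "gene"], observed=True).size()
        if (per < 2).any():
            raise ValidationError("need >= 2 Cq replicates per (sample, gene)")
        for sample, sub in self.data.groupby("sample", observed=True):
            for hk in self.housekeeping:
                if hk not in set(sub["gene"]):
                    raise ValidationError(
                        f"housekeeping gene {hk} missing in sample {sample}")


def generate_qpcr_table(true_fold_changes: dict[str, float], n_reps: int = 3,
                        noise_sd: float = 0.15, seed: int = 0,
                        n_samples_per_condition: int = 3,
                        housekeeping: tuple[str, str] = DEFAULT_HOUSEKEEPING,
                        ) -> CqTable:
    """Simulate Cq values with known mutant/WT fold changes.

    ``Cq = baseline(gene) - log2(fold) + N(0, noise_sd)`` with the fold
    applied only in mutant samples; housekeeping genes always have fold 1.
    """
    if n_reps < 2:
        raise ValidationError("n_reps must be >= 2")
    for hk in housekeeping:
        if true_fold_changes.get(hk, 1.0) != 1.0:
            raise ValidationError(f"housekeeping gene {hk} must have fold 1")
    if any(f <= 0 for f in true_fold_changes.values()):
        raise ValidationError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    genes = list(dict.fromkeys(list(true_fold_changes) + list(housekeeping)))
    baseline = {g: 18.0 + 8.0 * rng.random() for g in genes}
    rows = []
    for condition in (WT, MUT):
        for s in range(n_samples_per_condition):
            sample = f"{condition}-{s + 1}"
            for g in genes:
                fold = true_fold_changes.get(g, 1.0) if condition == MUT else 1.0
                mu = baseline[g] - np.log2(fold)
                for rep in range(n_reps):
                    noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                    rows.append({"sample": sample, "condition": condition,
                                 "gene": g, "replicate": rep + 1,
                                 "cq": mu + noise})
    return CqTable(pd.DataFrame(rows), housekeeping=housekeeping)


# ---------------------------------------------------------------------------
# On-disk export
# ---------------------------------------------------------------------------

def write_dataset(counts: CountMatrix, metadata: pd.DataFrame,
                  truth: GroundTruth, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write MTX + sidecars + cell_metadata.tsv + truth.tsv (+ gene sets)."""
    os.makedirs(out_dir, exist_ok=True)
    paths = write_counts(counts, out_dir)
    paths["cell_metadata"] = os.path.join(out_dir, "cell_metadata.tsv")
    metadata.to_csv(paths["cell_metadata"], sep="\t")
    paths["truth"] = os.path.join(out_dir, "truth.tsv")
    truth.to_frame().to_csv(paths["truth"], sep="\t")
    paths["binding_site_set"] = os.path.join(out_dir, "binding_site_genes.txt")
    with open(paths["binding_site_set"], "w") as fh:
        fh.write("\n".join(truth.binding_site_set) + "\n")
    paths["universe"] = os.path.join(out_dir, "gene_universe.txt")
    with open(paths["universe"], "w") as fh:
        fh.write("\n".join(truth.universe) + "\n")
    return paths


def default_spec(**overrides) -> SyntheticSpec:
    """The stock simulation conditions, with keyword overrides."""
    return replace(SyntheticSpec(), **overrides) if overrides else SyntheticSpec()
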