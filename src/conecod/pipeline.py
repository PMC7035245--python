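"""End-to-end orchestration: simulate/ingest -> QC -> annotate -> DE ->
enrichment -> pseudotime, with a machine-readable run report.

Each stage writes its outputs as plain TSV/MTX/JSON under the run's output
directory; a single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence`` so any stage re-run in isolation is
deterministic.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, enrichment, populations, qc, synthetic, trajectory
from .containers import (CountMatrix, ValidationError, read_cell_metadata,
                         read_counts)

logger = logging.getLogger(__name__)

PHOTORECEPTOR_POPULATIONS = ("rod", "ML-cone", "S-cone", "cod", "developing")


@dataclass
class Finding:
    level: str  # "error" | "warning"
    message: str


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Input is either a synthetic spec (``use_synthetic=True``) or paths to
    an MTX matrix with sidecars and a metadata TSV.
    """

    outdir: str = "conecod_run"
    seed: int = 0
    use_synthetic: bool = True
    synthetic_spec: synthetic.SyntheticSpec = field(
        default_factory=synthetic.SyntheticSpec)
    matrix_path: str | None = None
    genes_path: str | None = None
    barcodes_path: str | None = None
    metadata_path: str | None = None
    qc_config: qc.QCConfig = field(default_factory=qc.QCConfig)
    marker_panel: dict[str, list[str]] | None = None
    n_hvg: int = 1000
    n_clusters: int = 12
    n_pca: int = 20
    de_config: diffexpr.DEConfig = field(default_factory=diffexpr.DEConfig)
    enrichment_iterations: int = 1000
    binding_site_genes: list[str] | None = None  # synthetic truth if None
    ordering: trajectory.OrderingConfig = field(
        default_factory=lambda: trajectory.OrderingConfig(n_ordering_genes=200))
    n_centroids: int = 8
    run_trajectory: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "synthetic_spec" in kwargs:
            kwargs["synthetic_spec"] = synthetic.SyntheticSpec(
                **kwargs["synthetic_spec"])
        if "qc_config" in kwargs:
            kwargs["qc_config"] = qc.QCConfig(**kwargs["qc_config"])
        if "de_config" in kwargs:
            kwargs["de_config"] = diffexpr.DEConfig(**kwargs["de_config"])
        if "ordering" in kwargs:
            kwargs["ordering"] = trajectory.OrderingConfig(**kwargs["ordering"])
        return cls(**kwargs)


def validate(config: RunConfig) -> list[Finding]:
    """Schema / path / range checks; findings are returned, never raised."""
    findings: list[Finding] = []
    if not config.use_synthetic:
        for name in ("matrix_path", "genes_path", "barcodes_path",
                     "metadata_path"):
            path = getattr(config, name)
            if path is None:
                findings.append(Finding("error", f"{name} is required for "
                                        "non-synthetic runs"))
            elif not os.path.exists(path):
                findings.append(Finding("error", f"{name} does not exist: {path}"))
    try:
        config.qc_config.__post_init__()
    except ValidationError as exc:
        findings.append(Finding("error", f"qc_config: {exc}"))
    if config.marker_panel is not None:
        try:
            populations.validate_marker_panel(config.marker_panel)
        except ValidationError as exc:
            findings.append(Finding("error", f"marker_panel: {exc}"))
    if config.n_clusters < 2:
        findings.append(Finding("error", "n_clusters must be >= 2"))
    if config.enrichment_iterations < 2:
        findings.append(Finding("error", "enrichment_iterations must be >= 2"))
    if config.use_synthetic and config.binding_site_genes is not None:
        findings.append(Finding(
            "warning", "binding_site_genes overrides the synthetic truth set"))
    return findings


def _stage_seed(base_seed: int, stage: int) -> int:
    return int(np.random.SeedSequence(base_seed).generate_state(stage + 1)[-1]
               % (2 ** 31))


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run report (also written as
    ``report.json`` in the output directory)."""
    findings = validate(config)
    errors = [f.message for f in findings if f.level == "error"]
    if errors:
        raise ValidationError("invalid config: " + "; ".join(errors))
    t0 = time.time()
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {"config": {"seed": config.seed, "outdir": config.outdir,
                               "synthetic": config.use_synthetic},
                    "stages": {}, "outputs": {}}

    # -- stage 0: input ------------------------------------------------
    if config.use_synthetic:
        from dataclasses import replace as _replace
        spec = _replace(config.synthetic_spec, seed=_stage_seed(config.seed, 0))
        counts, metadata, truth = synthetic.generate_organoid_dataset(spec)
        paths = synthetic.write_dataset(counts, metadata, truth,
                                        os.path.join(config.outdir, "input"))
        report["outputs"].update(paths)
        binding_set = config.binding_site_genes or truth.binding_site_set
    else:
        counts = read_counts(config.matrix_path, config.genes_path,
                             config.barcodes_path)
        metadata = read_cell_metadata(config.metadata_path)
        truth = None
        binding_set = config.binding_site_genes or []
    report["stages"]["input"] = {"cells": counts.n_cells,
                                 "genes": counts.n_genes}
    logger.info("input: %d cells x %d genes", counts.n_cells, counts.n_genes)

    # -- stage 1: QC + normalization ----------------------------------
    ann = qc.compute_cell_qc(counts, config.qc_config.mito_prefix, metadata)
    counts_f, ann = qc.filter_cells(counts, ann, config.qc_config)
    counts_f = qc.filter_genes(counts_f, config.qc_config.min_cells_per_gene)
    norm = qc.normalize(counts_f)
    ann.to_csv(os.path.join(config.outdir, "cell_annotation.tsv"), sep="\t")
    report["stages"]["qc"] = {
        "cells_in": counts.n_cells, "cells_out": counts_f.n_cells,
        "genes_in": counts.n_genes, "genes_out": counts_f.n_genes}

    # -- stage 2: HVG + clustering + annotation ------------------------
    hvg = qc.select_hvg(norm, ann, n_top=config.n_hvg)
    k = min(config.n_clusters, max(2, counts_f.n_cells))
    clusters = populations.cluster_cells(norm, hvg, n_components=config.n_pca,
                                         k=k, seed=_stage_seed(config.seed, 2))
    annres = populations.annotate_clusters(norm, clusters, config.marker_panel)
    ann = ann.copy()
    ann["cluster_id"] = clusters
    ann["population"] = annres.per_cell(clusters)
    ann.to_csv(os.path.join(config.outdir, "cell_annotation.tsv"), sep="\t")
    report["stages"]["annotate"] = {
        "n_hvg": len(hvg), "k": int(k),
        "populations": sorted(set(annres.population.values())),
        "ambiguous_clusters": sorted(annres.ambiguous)}

    genotype = ann["genotype"].to_numpy()
    popl = ann["population"].to_numpy()

    # -- stage 3: expression summary (diagnostic markers) ---------------
    focus = [g for g in ("OPN1SW", "OPN1MW", "NR2E3")
             if g in norm.gene_index()]
    groups = {g: genotype == g for g in np.unique(genotype)}
    summary = populations.summary_table(counts_f, norm, focus, groups)
    summary.to_csv(os.path.join(config.outdir, "expression_summary.tsv"),
                   sep="\t", index=False)
    report["stages"]["summary"] = summary.to_dict("records")

    # -- stage 4: per-population genotype DE ----------------------------
    de_counts = {}
    for pop in sorted(set(popl)):
        mask_wt = (popl == pop) & (genotype == synthetic.WT)
        mask_mut = (popl == pop) & (genotype == synthetic.MUT)
        if (mask_wt.sum() < config.de_config.min_cells_per_group
                or mask_mut.sum() < config.de_config.min_cells_per_group):
            continue
        de = diffexpr.de_between_groups(norm, mask_wt, mask_mut,
                                        config.de_config)
        de.to_csv(os.path.join(config.outdir, f"de_{pop}.tsv"), sep="\t",
                  index=False)
        de_counts[pop] = int(de["significant"].sum())
    report["stages"]["de"] = de_counts

    # -- stage 5: cod tri-classification --------------------------------
    tri_table = None
    q_mask = (popl == "cod") & (genotype == synthetic.MUT)
    rod_mask = (popl == "rod") & (genotype == synthetic.WT)
    cone_mask = (popl == "ML-cone") & (genotype == synthetic.WT)
    if q_mask.any() and rod_mask.any() and cone_mask.any():
        tri_table = diffexpr.tri_compare(norm, q_mask, rod_mask, cone_mask,
                                         config.de_config)
        tri_table.to_csv(os.path.join(config.outdir, "tri_compare.tsv"),
                         sep="\t", index=False)
        report["stages"]["tri_compare"] = (
            tri_table["class"].value_counts().to_dict())
        de_genes = tri_table.loc[tri_table["class"] != "ns", "gene"].tolist()
    else:
        report["stages"]["tri_compare"] = "skipped: missing cod/rod/cone cells"
        de_genes = []

    # -- stage 6: binding-site enrichment -------------------------------
    if binding_set and de_genes:
        universe = [str(g) for g in norm.gene_ids]
        inp = enrichment.EnrichmentInput(
            universe=universe,
            target_set=enrichment.GeneSet("binding-site",
                                          [g for g in binding_set]),
            selection=[g for g in de_genes if g in set(universe)],
            n_iterations=config.enrichment_iterations,
            seed=_stage_seed(config.seed, 6))
        res = enrichment.enrichment_test(inp)
        report["stages"]["enrichment"] = res.summary()
        with open(os.path.join(config.outdir, "enrichment.json"), "w") as fh:
            json.dump(res.summary(), fh, indent=2)
    else:
        report["stages"]["enrichment"] = "skipped: no target set or DE genes"

    # -- stage 7: WT photoreceptor trajectory ---------------------------
    if config.run_trajectory:
        pr_mask = (np.isin(popl, PHOTORECEPTOR_POPULATIONS)
                   & (genotype == synthetic.WT))
        if pr_mask.sum() >= 3 * config.n_centroids:
            idx = np.flatnonzero(pr_mask)
            raw_pr = counts_f.subset_cells(idx)
            labels = pd.DataFrame({
                "age_day": ann["age_day"].to_numpy()[idx],
                "coarse_type": trajectory.coarse_type_labels(raw_pr).to_numpy(),
            })
            try:
                ordering = trajectory.select_ordering_genes(
                    raw_pr, labels, config.ordering)
                norm_pr = qc.normalize(raw_pr)
                traj = trajectory.build_trajectory(
                    norm_pr, ordering, n_centroids=config.n_centroids,
                    seed=_stage_seed(config.seed, 7))
                pd.DataFrame({"barcode": raw_pr.barcodes,
                              "pseudotime": traj.pseudotime,
                              "state": traj.state,
                              "branch": traj.branch}).to_csv(
                    os.path.join(config.outdir, "trajectory.tsv"),
                    sep="\t", index=False)
                report["stages"]["trajectory"] = {
                    "cells": int(pr_mask.sum()),
                    "n_ordering_genes": len(ordering),
                    "n_states": int(len(np.unique(traj.state))),
                    "branches": sorted(set(traj.branch))}
            except ValidationError as exc:
                report["stages"]["trajectory"] = f"skipped: {exc}"
        else:
            report["stages"]["trajectory"] = "skipped: too few WT photoreceptors"

    report["wall_time_s"] = round(time.time() - t0, 2)
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
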