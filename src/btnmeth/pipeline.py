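"""End-to-end orchestration of the synthetic "study run".

``run_all`` chains every stage — simulate, window profiling, stepwise model
selection, differential methylation, expression coupling, retroelement
scanning and insertion filtering — over a lineage trio plus the
mixed-purity cohort, writing each stage's tables under an output directory
and returning a manifest of inputs, outputs and per-stage status.  Re-runs
with the same config and seed reproduce identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .diffmeth import bimodal_split, differential_genes, dip_test, gene_matrix, hierarchical_cluster
from .expression import methylated_cpg_proportion, methylation_expression_correlation, tpm_table
from .modelsel import stepwise_aic
from .profiling import compare_distributions, feature_distribution, genome_summary, window_profile
from .te import divergence_landscape, element_methylation, filter_insertions, nj_tree, scan_copies
from .sim import (PRESETS, cohort_plan, consensus_elements, simulate_expression,
                  simulate_genome, simulate_insertion_callset, simulate_methylome,
                  simulate_te_copies)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "preset": "healthy",
    "window_size": 100_000,
    "min_cpg": 3,
    "p_thresh": 0.05,
    "lfc_thresh": 1.0,
    "methylated_site_threshold": 0.5,
    "te_min_id": 0.80,
    "te_full_cov": 0.90,
    "insertion_min_support": 4,
}

MODEL_CANDIDATES = ["gene", "cpg_island", "tandem", "satellite", "n_frac", "gc_frac"]
_RENAME = {"gene_frac": "gene", "cpg_island_frac": "cpg_island",
           "tandem_repeat_frac": "tandem", "satellite_frac": "satellite",
           "mean_hmc": "hmc"}


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    outputs: dict = field(default_factory=dict)   # stage -> list of paths
    status: dict = field(default_factory=dict)    # stage -> "ok" / error text
    summaries: dict = field(default_factory=dict)

    def record(self, stage: str, paths, **summary):
        paths = [str(p) for p in (paths if isinstance(paths, (list, tuple)) else [paths])]
        for p in paths:
            if not Path(p).exists() or Path(p).stat().st_size == 0:
                raise RuntimeError(f"stage {stage} produced missing/empty output {p}")
        self.outputs[stage] = paths
        self.status[stage] = "ok"
        self.summaries.setdefault(stage, {}).update(summary)


def profile_table(sg, calls, window_size: int = 100_000) -> pd.DataFrame:
    """Window table with the covariate names the models use."""
    tracks = {k: sg.tracks[k] for k in
              ("gene", "cpg_island", "tandem_repeat", "satellite")}
    prof = window_profile(calls, sg.genome, tracks, window_size).rename(columns=_RENAME)
    prof["mean_hmc"] = prof["hmc"]  # keep the canonical channel name too
    return prof


def run_all(config: dict | None = None, seed: int = 0, outdir=None) -> RunManifest:
    """Run the whole synthetic analysis; see module docstring."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    outdir = Path(outdir or "btnmeth_run")
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]
    manifest = RunManifest(version=__version__, config_hash=cfg_hash, seed=seed)
    consensus = consensus_elements()

    stage = "simulate"
    try:
        preset = PRESETS[cfg["preset"]]
        sg = simulate_genome(preset, seed)
        fasta = io.write_fasta(sg.genome, outdir / "genome.fa")
        beds = []
        for name, track in sg.tracks.items():
            beds.append(io.write_bed(track, outdir / f"track_{name}.bed"))
        calls, sample_truth = simulate_methylome(sg, preset, seed, cfg["preset"],
                                                 purity=0.0 if cfg["preset"] == "healthy" else 1.0,
                                                 tumour_preset=None if cfg["preset"] == "healthy" else preset)
        methyl = io.write_methyl_table(calls, outdir / "methylome.tsv")
        manifest.record(stage, [fasta, methyl, *beds], n_sites=len(calls))
    except Exception as exc:  # noqa: BLE001 - abort naming the failing stage
        manifest.status[stage] = f"failed: {exc}"
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "profile"
    prof = profile_table(sg, calls, cfg["window_size"])
    prof_path = io.write_tsv(prof, outdir / "windows.tsv")
    mc_mean, mc_sd = genome_summary(prof, "window", "mc")
    hmc_mean, hmc_sd = genome_summary(prof, "window", "hmc")
    sat_dist = feature_distribution(calls, sg.tracks["satellite"], min_cpg=cfg["min_cpg"])
    gene_dist = feature_distribution(calls, sg.tracks["gene"], min_cpg=cfg["min_cpg"])
    comp = compare_distributions(gene_dist, sat_dist) if len(sat_dist) else None
    manifest.record(stage, prof_path, window_mc=mc_mean, window_mc_sd=mc_sd,
                    window_hmc=hmc_mean, window_hmc_sd=hmc_sd,
                    gene_vs_satellite_star=(comp.star if comp else "na"))

    stage = "modelsel"
    res_m = stepwise_aic(prof, prof["mean_mc"].to_numpy(), MODEL_CANDIDATES + ["hmc"])
    res_h = stepwise_aic(prof, prof["hmc"].to_numpy(), MODEL_CANDIDATES)
    coef = pd.DataFrame([
        {"response": resp, "predictor": p, "coefficient": r.coefficients[p],
         "standardized": r.standardized[p]}
        for resp, r in (("mean_mc", res_m), ("mean_hmc", res_h))
        for p in r.selected
    ])
    coef_path = io.write_tsv(coef, outdir / "model_coefficients.tsv")
    traj_path = outdir / "model_trajectories.json"
    traj_path.write_text(json.dumps({
        "mean_mc": list(res_m.aic_trajectory), "mean_hmc": list(res_h.aic_trajectory)}))
    manifest.record(stage, [coef_path, traj_path],
                    mc_signs=res_m.signs, hmc_signs=res_h.signs,
                    strongest=res_m.strongest_predictor)

    stage = "diffmeth"
    plan = cohort_plan()
    calls_by, meta_rows = {}, []
    for s in plan:
        c, _ = simulate_methylome(sg, PRESETS["healthy"], seed, s.sample_id,
                                  s.tumour_purity,
                                  PRESETS["cedbtn1"] if s.tumour_purity else None)
        calls_by[s.sample_id] = c
        meta_rows.append({"sample_id": s.sample_id, "lineage": s.lineage,
                          "tissue": s.tissue, "intensity": s.intensity})
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    gm = gene_matrix(calls_by, sg.tracks["gene"], meta, min_cpg=cfg["min_cpg"])
    healthy_ids = list(meta.index[meta["lineage"] == "healthy"])
    tumour_ids = list(meta.index[meta["lineage"] != "healthy"])
    dg = differential_genes(gm, healthy_ids, tumour_ids,
                            cfg["p_thresh"], cfg["lfc_thresh"])
    dg_path = io.write_tsv(dg, outdir / "differential_genes.tsv")
    cl = hierarchical_cluster(gm, k=3)
    labels_path = io.write_tsv(cl.sample_labels.rename("cluster").reset_index(),
                               outdir / "cluster_labels.tsv")
    healthy_gene_means = gm.values[healthy_ids[0]].dropna()
    dip = dip_test(healthy_gene_means, n_boot=500, seed=seed)
    split = bimodal_split(healthy_gene_means, seed=seed)
    manifest.record(stage, [dg_path, labels_path],
                    n_differential=int((dg["class"] != "ns").sum()),
                    dip_statistic=dip.statistic, dip_p=dip.p_value,
                    low_mode=split.low_mean, high_mode=split.high_mean)

    stage = "exprlink"
    prop = methylated_cpg_proportion(calls, sg.tracks["gene"],
                                     cfg["methylated_site_threshold"], cfg["min_cpg"])
    counts = simulate_expression(sg, sample_truth["gene_true_prop"], preset, seed)
    counts_path = io.write_expression_table(counts, outdir / "expression_counts.tsv")
    expr = tpm_table(counts).set_index("gene_id")
    corr = methylation_expression_correlation(prop, expr["tpm"])
    pairs = pd.DataFrame({"gene_id": prop.index, "methylated_cpg_proportion": prop.values}
                         ).merge(expr.reset_index()[["gene_id", "tpm"]], on="gene_id")
    pairs_path = io.write_tsv(pairs, outdir / "methylation_expression_pairs.tsv")
    (outdir / "expression_summary.json").write_text(json.dumps(
        {"pearson_r": corr.pearson_r, "p_value": corr.p_value, "n": corr.n}))
    manifest.record(stage, [counts_path, pairs_path, outdir / "expression_summary.json"],
                    pearson_r=corr.pearson_r)

    stage = "te-scan"
    scan_outputs, te_summary = [], {}
    for fam, cons in consensus.items():
        copies = scan_copies(sg.genome, cons, cfg["te_min_id"], cfg["te_full_cov"])
        bed = io.write_bed(
            type(sg.tracks["te"]).from_intervals("te", [
                (c.contig, c.start, c.end, c.strand, c.copy_id) for c in copies]),
            outdir / f"copies_{fam}.bed") if copies else None
        land = divergence_landscape(copies, cons, sg.config.genome_size)
        land_path = io.write_tsv(pd.DataFrame({
            "bin_low_percent": land.bin_edges[:-1] * 100,
            "coverage_percent": land.coverage_percent}), outdir / f"landscape_{fam}.tsv")
        scan_outputs.extend([p for p in (bed, land_path) if p])
        te_summary[fam] = {"n_copies": len(copies),
                           "n_full_length": sum(c.is_full_length for c in copies),
                           "coverage_percent": land.total_percent}
        if copies and any(True for _ in copies):
            em = element_methylation(calls, copies)
            te_summary[fam]["element_mc"] = em.mean
    cs = simulate_te_copies(consensus["CedCL34"], {"healthy": 6, "cedbtn1": 8, "cedbtn2": 8}, seed)
    labels = cs.labels
    D = np.zeros((len(labels), len(labels)))
    from .te import kimura_distance
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            D[i, j] = D[j, i] = kimura_distance(cs.sequences[a], cs.sequences[labels[j]])
    tree_path = io.write_newick(nj_tree(D, labels), outdir / "cl34_nj.nwk")
    scan_outputs.append(tree_path)
    manifest.record(stage, scan_outputs, **te_summary)

    stage = "te-insertions"
    ins_preset = PRESETS["cedbtn2"]
    sg2 = simulate_genome(ins_preset, seed)
    vcf_calls = simulate_insertion_callset(sg2, ins_preset, seed)
    vcf_path = io.write_insertion_vcf(vcf_calls, sg2.contig_lengths, outdir / "insertions.vcf")
    loaded = io.read_insertion_vcf(vcf_path)
    filt = filter_insertions(loaded, list(consensus.values()),
                             min_support=cfg["insertion_min_support"])
    kept = pd.DataFrame([{"record_id": k.call.record_id, "family": k.family,
                          "tandem_count": k.tandem_count,
                          "needs_validation": k.needs_validation} for k in filt.kept])
    rej = pd.DataFrame([{"record_id": c.record_id, "reason": r} for c, r in filt.rejected])
    kept_path = io.write_tsv(kept, outdir / "insertions_kept.tsv")
    rej_path = io.write_tsv(rej, outdir / "insertions_rejected.tsv")
    manifest.record(stage, [vcf_path, kept_path, rej_path],
                    kept_cl34=len(filt.kept_by_family("CedCL34")),
                    kept_cl24=len(filt.kept_by_family("CedCL24")),
                    n_rejected=len(filt.rejected))

    (outdir / "manifest.json").write_text(json.dumps({
        "version": manifest.version, "config_hash": manifest.config_hash,
        "seed": manifest.seed, "outputs": manifest.outputs,
        "status": manifest.status,
        "summaries": json.loads(json.dumps(manifest.summaries, default=float)),
    }, indent=2))
    return manifest
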