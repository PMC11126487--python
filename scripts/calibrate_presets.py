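"""One-off calibration of the lineage presets.

Iteratively adjusts each preset's free location parameters — the intergenic
5mC baseline, the 5hmC baseline, the high-gene-mode location, and the
expression noise SD — until the simulated lineage reproduces its documented
summary statistics through the actual analysis pipeline (window profiling,
EM bimodal split, methylation-expression correlation).  The resulting
numbers are frozen into ``btnmeth/sim/presets.py``; this script is kept so
the calibration is reproducible, it is not part of routine runs.

Usage:  python scripts/calibrate_presets.py
"""

from __future__ import annotations

import dataclasses

import numpy as np

from btnmeth.diffmeth import bimodal_split, gene_matrix
from btnmeth.expression import (methylated_cpg_proportion,
                                methylation_expression_correlation, tpm_table)
from btnmeth.profiling import genome_summary, window_profile
from btnmeth.sim import PRESETS, simulate_expression, simulate_genome, simulate_methylome

SEEDS = (11, 12)
ROUNDS = 3


def measure(preset, seed):
    sg = simulate_genome(preset, seed)
    purity = 0.0 if preset.name == "healthy" else 1.0
    tp = None if purity == 0 else preset
    calls, st = simulate_methylome(sg, PRESETS["healthy"] if purity else preset,
                                   seed, f"{preset.name}_cal", purity, tp)
    prof = window_profile(calls, sg.genome)
    mc, _ = genome_summary(prof, "window", "mc")
    hmc, _ = genome_summary(prof, "window", "hmc")

    # intergenic site share (the 5mC baseline response fraction)
    idx = sg.site_index
    n_tot = sum(len(v["pos"]) for v in idx.values())
    n_int = sum(int((v["cls"] == 0).sum()) for v in idx.values())

    out = {"mc": mc, "hmc": hmc, "share_int": n_int / n_tot}

    if preset.name == "healthy":
        gm = gene_matrix({"s": calls}, sg.tracks["gene"])
        split = bimodal_split(gm.values["s"], seed=0)
        out["high_mode"] = split.high_mean
        out["low_mode"] = split.low_mean
    prop = methylated_cpg_proportion(calls, sg.tracks["gene"])
    expr = tpm_table(simulate_expression(sg, st["gene_true_prop"], preset, seed))
    r = methylation_expression_correlation(
        prop, expr.set_index("gene_id")["tpm"]).pearson_r
    out["r"] = r
    out["varP"] = float(np.var(st["gene_true_prop"].to_numpy()))
    return out


def main():
    for name in ("healthy", "cedbtn1", "cedbtn2"):
        preset = PRESETS[name]
        t = preset.targets
        for rnd in range(ROUNDS):
            ms = [measure(preset, s) for s in SEEDS]
            avg = {k: float(np.mean([m[k] for m in ms])) for k in ms[0]}
            upd = {}
            upd["intergenic_mc"] = preset.intergenic_mc + (
                t["window_mc_percent"] / 100 - avg["mc"]) / avg["share_int"]
            upd["intergenic_hmc"] = preset.intergenic_hmc + (
                t["window_hmc_percent"] / 100 - avg["hmc"]) / 0.99
            if "gene_high_mode_percent" in t:
                upd["gene_high_loc"] = preset.gene_high_loc + (
                    t["gene_high_mode_percent"] / 100 - avg["high_mode"])
                upd["gene_low_loc"] = preset.gene_low_loc + (
                    t["gene_low_mode_percent"] / 100 - avg["low_mode"])
            # expression noise: match implied total-noise variance for target r
            b2v = preset.expr_beta**2 * avg["varP"]
            r_now, r_tgt = max(avg["r"], 0.05), t["expression_r"]
            extra_now = b2v * (1 - r_now**2) / r_now**2 - (
                preset.expr_sigma**2 if False else 0)
            noise_now = b2v * (1 - r_now**2) / r_now**2
            noise_tgt = b2v * (1 - r_tgt**2) / r_tgt**2
            sig2 = preset.expr_sigma**2 + (noise_tgt - noise_now)
            upd["expr_sigma"] = float(np.sqrt(max(sig2, 0.04)))
            preset = dataclasses.replace(preset, **upd)
            print(f"{name} round {rnd}: measured {avg} -> "
                  f"b0={preset.intergenic_mc:.4f} h0={preset.intergenic_hmc:.4f} "
                  f"high={preset.gene_high_loc:.4f} low={preset.gene_low_loc:.4f} "
                  f"sigma={preset.expr_sigma:.3f}")
        final = [measure(preset, s) for s in (21, 22, 23)]
        print(f"{name} FINAL check:",
              {k: round(float(np.mean([m[k] for m in final])), 4)
               for k in final[0] if k != "share_int"})


if __name__ == "__main__":
    main()
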