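"""Desk-scale genome simulation: sequence, annotation tracks, planted truth.

Window-level composition (GC, gene density, CpG islands, tandem arrays,
N-blocks, one satellite array) follows the fixed layout patterns from
``presets``; the user seed controls sequence content, placements within
windows, gene-mode assignment and gene-mode values.  Gene modes are drawn
with stratified (quantile-balanced) sampling and dealt across windows with
a low-discrepancy stride so genome-level summaries are stable across seeds
while windows still differ strongly in composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ..features import FeatureTrack, enumerate_cpg_sites
from ..io import GenomeSequence
from .consensus import (
    consensus_elements,
    cpg_rich_dna,
    mutate,
    random_dna,
    satellite_monomer,
    tandem_monomer,
)
from .presets import GenomeConfig, LineagePreset, layout_patterns

SITE_CLASS = {"intergenic": 0, "gene": 1, "cpg_island": 2, "tandem": 3,
              "satellite": 4, "te": 5}
_MIN_GAP = 400


@dataclass
class SimulatedGenome:
    genome: list                  # list[GenomeSequence]
    tracks: dict                  # feature_class -> FeatureTrack
    truth: dict                   # planted parameters (genes table, TE loci, patterns)
    config: GenomeConfig
    preset_name: str
    site_index: dict = field(default_factory=dict)  # contig -> per-CpG annotation arrays

    @property
    def contig_lengths(self) -> dict:
        return {g.contig_id: len(g.sequence) for g in self.genome}


def _stratified_truncnorm(rng, n, loc, scale, lo=0.002, hi=0.998) -> np.ndarray:
    """Quantile-balanced draws from a truncated normal (sorted)."""
    a, b = (lo - loc) / scale, (hi - loc) / scale
    u = (np.arange(n) + rng.uniform(0.2, 0.8, size=n)) / n
    return stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)


def _deal(sorted_values: np.ndarray) -> np.ndarray:
    """Low-discrepancy dealing: neighbours in input order get spread quantiles."""
    n = len(sorted_values)
    if n <= 2:
        return sorted_values
    stride = max(1, round(n * 0.6180339887))
    while np.gcd(stride, n) != 1:
        stride += 1
    return sorted_values[(np.arange(n) * stride) % n]


def _plan_te_windows(config: GenomeConfig, pats, te_plan) -> dict[int, list]:
    """Assign TE plant items to windows greedily by projected load."""
    n = config.n_windows
    W = config.window_size
    load = (pats["gene_frac"] * W + pats["island_count"] * 650
            + pats["tandem_frac"] * W + pats["nblock_count"] * 500.0)
    load = load.copy()
    load[pats["satellite_window"]] += 40_000
    assignment: dict[int, list] = {w: [] for w in range(n)}
    items = sorted(enumerate(te_plan), key=lambda kv: -(kv[1].c_end - kv[1].c_start))
    for idx, item in items:
        length = item.c_end - item.c_start
        order = np.argsort(load, kind="stable")
        for w in order:
            if load[w] + length + _MIN_GAP <= 0.90 * W:
                assignment[int(w)].append((idx, item))
                load[w] += length + _MIN_GAP
                break
        else:
            raise ValueError("TE plan exceeds genome capacity")
    return assignment


def _gene_structure(start: int, length: int):
    """(utr5, exons, introns, utr3) intervals of one gene, 0-based half-open."""
    utr5 = (start, start + 150)
    utr3 = (start + length - 250, start + length)
    pos = utr5[1]
    exons, introns = [], []
    core_end = utr3[0]
    toggle_exon = True
    while pos < core_end:
        span = 300 if toggle_exon else 500
        end = min(pos + span, core_end)
        (exons if toggle_exon else introns).append((pos, end))
        pos = end
        toggle_exon = not toggle_exon
    return utr5, exons, introns, utr3


def simulate_genome(preset: LineagePreset, seed: int,
                    config: GenomeConfig | None = None) -> SimulatedGenome:
    """Simulate the reference genome and all annotation tracks for a preset."""
    config = config or GenomeConfig()
    pats = layout_patterns(config)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    W = config.window_size
    wins_per_contig = config.contig_length // W
    consensus = consensus_elements()

    # shared ancestors for plan items with pre-split divergence
    ancestors = {}
    for item in preset.te_plan:
        key = (item.family, item.shared_divergence)
        if item.shared_divergence > 0 and key not in ancestors:
            ancestors[key] = mutate(consensus[item.family].sequence,
                                    item.shared_divergence, rng)

    te_assignment = _plan_te_windows(config, pats, preset.te_plan)

    contigs: list[GenomeSequence] = []
    placed_all: dict[str, list] = {}
    gene_rows = []
    te_rows = []
    intervals = {k: [] for k in ("gene", "exon", "intron", "utr5", "utr3", "te",
                                 "tandem_repeat", "satellite", "cpg_island", "n_block")}

    for ci in range(config.n_contigs):
        contig = f"chr{ci + 1}"
        seq = np.frombuffer(random_dna(rng, config.contig_length, 0.42).encode(),
                            dtype=np.uint8).copy()
        placed: list[dict] = []
        for wi in range(wins_per_contig):
            w_global = ci * wins_per_contig + wi
            w_start = wi * W
            # regenerate the window background at its designed GC
            gc = float(pats["gc"][w_global])
            seq[w_start:w_start + W] = np.frombuffer(
                random_dna(rng, W, gc).encode(), dtype=np.uint8)

            items: list[tuple] = []
            if ci == 0 and wi == pats["satellite_window"]:
                items.append(("satellite", 40_000, None))
            for _ in range(int(pats["nblock_count"][w_global])):
                items.append(("n_block", 500, None))
            for _ in range(int(pats["island_count"][w_global])):
                items.append(("cpg_island", int(rng.integers(500, 800)), None))
            tandem_left = int(pats["tandem_frac"][w_global] * W)
            while tandem_left >= 1500:
                ln = int(min(rng.integers(1500, 2500), tandem_left))
                items.append(("tandem", ln, None))
                tandem_left -= ln
            for idx, item in te_assignment[w_global]:
                items.append(("te", item.c_end - item.c_start, (idx, item)))
            fixed = sum(ln for _, ln, _ in items)
            gene_budget = int(pats["gene_frac"][w_global] * W)
            capacity = int(0.92 * W) - fixed - _MIN_GAP * (len(items) + 4)
            gene_budget = max(0, min(gene_budget, capacity))
            while gene_budget >= 2400:
                ln = int(min(rng.integers(2400, 5000), gene_budget))
                if ln < 2400:
                    break
                items.append(("gene", ln, None))
                gene_budget -= ln

            order = rng.permutation(len(items))
            items = [items[i] for i in order]
            total = sum(ln for _, ln, _ in items)
            slack = W - total - _MIN_GAP * (len(items) + 1)
            gaps = rng.dirichlet(np.ones(len(items) + 1)) * max(slack, 0) + _MIN_GAP
            pos = w_start
            for (kind, ln, meta), gap in zip(items, gaps):
                pos += int(gap)
                start, end = pos, pos + ln
                placed.append({"kind": kind, "start": start, "end": end,
                               "meta": meta, "window": w_global})
                pos = end
        placed.sort(key=lambda p: p["start"])

        # write feature sequences and record intervals
        for p in placed:
            start, end, kind = p["start"], p["end"], p["kind"]
            ln = end - start
            if kind == "n_block":
                seq[start:end] = ord("N")
                intervals["n_block"].append((contig, start, end, ".", f"nb_{contig}_{start}"))
            elif kind == "cpg_island":
                seq[start:end] = np.frombuffer(
                    cpg_rich_dna(rng, ln).encode(), dtype=np.uint8)
                intervals["cpg_island"].append((contig, start, end, ".", f"isl_{contig}_{start}"))
            elif kind == "satellite":
                mono = satellite_monomer()
                tiled = (mono * (ln // len(mono) + 1))[:ln]
                seq[start:end] = np.frombuffer(tiled.encode(), dtype=np.uint8)
                intervals["satellite"].append((contig, start, end, ".", f"sat_{contig}_{start}"))
            elif kind == "tandem":
                mono = tandem_monomer()
                tiled = (mono * (ln // len(mono) + 1))[:ln]
                seq[start:end] = np.frombuffer(tiled.encode(), dtype=np.uint8)
                intervals["tandem_repeat"].append((contig, start, end, ".", f"tan_{contig}_{start}"))
            elif kind == "te":
                idx, item = p["meta"]
                key = (item.family, item.shared_divergence)
                base = ancestors.get(key, consensus[item.family].sequence)
                copy = mutate(base[item.c_start:item.c_end], item.divergence, rng)
                if item.strand == "-":
                    from ..te import revcomp
                    copy = revcomp(copy)
                seq[start:end] = np.frombuffer(copy.encode(), dtype=np.uint8)
                name = f"{item.family}_{contig}_{start}"
                intervals["te"].append((contig, start, end, item.strand, name))
                te_rows.append({"family": item.family, "contig": contig,
                                "start": start, "end": end, "strand": item.strand,
                                "c_start": item.c_start, "c_end": item.c_end,
                                "divergence": item.divergence,
                                "shared_divergence": item.shared_divergence,
                                "full_length": (item.c_end - item.c_start)
                                >= 0.90 * len(consensus[item.family].sequence)
                                and item.divergence + item.shared_divergence <= 0.10})
            elif kind == "gene":
                gid = f"gene_{contig}_{start}"
                strand = "+" if rng.random() < 0.5 else "-"
                utr5, exons, introns, utr3 = _gene_structure(start, ln)
                intervals["gene"].append((contig, start, end, strand, gid))
                intervals["utr5"].append((contig, *utr5, strand, f"{gid}_utr5"))
                intervals["utr3"].append((contig, *utr3, strand, f"{gid}_utr3"))
                for i, (s, e) in enumerate(exons):
                    intervals["exon"].append((contig, s, e, strand, f"{gid}_ex{i}"))
                for i, (s, e) in enumerate(introns):
                    intervals["intron"].append((contig, s, e, strand, f"{gid}_in{i}"))
                gene_rows.append({"gene_id": gid, "contig": contig, "start": start,
                                  "end": end, "length": ln, "window": p["window"]})
        placed_all[contig] = placed
        contigs.append(GenomeSequence(contig, seq.tobytes().decode()))

    tracks = {k: FeatureTrack.from_intervals(
        "tandem_repeat" if k == "tandem_repeat" else k, v)
        for k, v in intervals.items()}
    tracks["intergenic"] = tracks["gene"].complement(contigs, "intergenic")

    genes = pd.DataFrame(gene_rows)
    genes = _assign_gene_modes(genes, preset, config, rng)

    truth = {
        "genes": genes,
        "te_loci": pd.DataFrame(te_rows),
        "patterns": pats,
        "preset": preset.name,
        "seed": seed,
    }
    sg = SimulatedGenome(genome=contigs, tracks=tracks, truth=truth,
                         config=config, preset_name=preset.name)
    sg.site_index = _build_site_index(sg, placed_all, genes)
    return sg


def _assign_gene_modes(genes: pd.DataFrame, preset: LineagePreset,
                       config: GenomeConfig, rng) -> pd.DataFrame:
    """Bimodal mode assignment and host/tumour gene values.

    High/low counts are stratified per window (carry rounding) and values
    are dealt with a low-discrepancy stride, so window and genome summaries
    of the mixture are nearly free of sampling noise.
    """
    genes = genes.sort_values(["window", "start"], ignore_index=True)
    n = len(genes)
    is_high = np.zeros(n, dtype=bool)
    carry = 0.0
    for w, grp in genes.groupby("window"):
        k = preset.p_high * len(grp) + carry
        k_int = int(np.floor(k))
        carry = k - k_int
        pick = rng.choice(grp.index.to_numpy(), size=min(k_int, len(grp)), replace=False)
        is_high[pick] = True
    genes["mode"] = np.where(is_high, "high", "low")

    n_high, n_low = int(is_high.sum()), int((~is_high).sum())
    high_vals = _deal(_stratified_truncnorm(rng, n_high, preset.gene_high_loc,
                                            preset.gene_high_sd))
    low_vals = _deal(_stratified_truncnorm(rng, n_low, preset.gene_low_loc,
                                           preset.gene_low_sd))
    host = np.empty(n)
    host[is_high] = high_vals
    host[~is_high] = low_vals
    genes["host_value"] = host

    # differential genes: hypermethylated-in-host genes silenced in the
    # tumour profile ("down") and host-silent genes methylated there ("up").
    # Candidates come from clearly-methylated host modes (>= 0.28), and "up"
    # tumour values are drawn away from the mode boundary, so the planted
    # effects always clear a one-unit fold-change gate even after purity
    # dilution of the tumour group.
    diff = np.array(["none"] * n, dtype=object)
    high_idx = np.flatnonzero(is_high & (host >= 0.28))
    low_idx = np.flatnonzero(~is_high)
    down_pick = rng.choice(high_idx, size=min(config.n_diff_down, len(high_idx)),
                           replace=False)
    up_pick = rng.choice(low_idx, size=min(config.n_diff_up, len(low_idx)),
                         replace=False)
    diff[down_pick] = "down"
    diff[up_pick] = "up"
    genes["diff_class"] = diff

    tumour = host.copy()
    tumour[is_high] *= preset.tumour_gene_scale
    tumour[down_pick] = _stratified_truncnorm(rng, len(down_pick),
                                              preset.gene_low_loc,
                                              preset.gene_low_sd)
    tumour[up_pick] = _stratified_truncnorm(rng, len(up_pick),
                                            preset.gene_high_loc,
                                            preset.gene_high_sd, lo=0.2)
    genes["tumour_value"] = tumour
    return genes


def _build_site_index(sg: SimulatedGenome, placed_all, genes: pd.DataFrame) -> dict:
    """Per-CpG annotation arrays: class, gene row, TE family, window index."""
    sites = enumerate_cpg_sites(sg.genome)
    W = sg.config.window_size
    wins_per_contig = sg.config.contig_length // W
    gene_lookup = {(r.contig, r.start): i for i, r in genes.iterrows()}
    te_families = sorted({r["meta"][1].family for p in placed_all.values()
                          for r in p if r["kind"] == "te"} | set())
    fam_code = {f: i for i, f in enumerate(te_families)}
    out = {}
    for ci, g in enumerate(sg.genome):
        pos = sites[g.contig_id]
        cls = np.zeros(len(pos), dtype=np.int8)
        gene_idx = np.full(len(pos), -1, dtype=np.int64)
        te_fam = np.full(len(pos), -1, dtype=np.int8)
        for p in placed_all[g.contig_id]:
            lo, hi = np.searchsorted(pos, [p["start"], p["end"]])
            kind = p["kind"]
            if kind == "gene":
                cls[lo:hi] = SITE_CLASS["gene"]
                gene_idx[lo:hi] = gene_lookup[(g.contig_id, p["start"])]
            elif kind == "cpg_island":
                cls[lo:hi] = SITE_CLASS["cpg_island"]
            elif kind == "tandem":
                cls[lo:hi] = SITE_CLASS["tandem"]
            elif kind == "satellite":
                cls[lo:hi] = SITE_CLASS["satellite"]
            elif kind == "te":
                cls[lo:hi] = SITE_CLASS["te"]
                te_fam[lo:hi] = fam_code[p["meta"][1].family]
        window = (pos // W) + ci * wins_per_contig
        out[g.contig_id] = {
            "pos": pos, "cls": cls, "gene_idx": gene_idx,
            "te_family": te_fam, "window": window,
            "te_family_names": te_families,
        }
    return out
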