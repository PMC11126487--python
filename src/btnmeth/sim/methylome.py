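"""Per-CpG 5mC/5hmC call simulation with depth-dependent binomial noise.

Every CpG site gets a regional mean from its feature context (gene mode,
CpG island, tandem repeat, satellite desert, retroelement family, or the
intergenic baseline modulated by the window's GC / N-block / latent-factor
pattern).  True site levels are Beta-distributed around the regional mean,
read depth is Poisson, and the reported fractions are binomial counts over
that depth — 5mC and 5hmC drawn jointly so their sum never exceeds the
depth.  Mixed-purity samples interpolate the site means of a host and a
tumour profile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import SITE_CLASS, SimulatedGenome
from .presets import REGIONAL_COEF, LineagePreset


def site_means(sg: SimulatedGenome, preset: LineagePreset,
               profile: str = "host") -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """(mu_5mC, mu_5hmC) per CpG site for one lineage profile.

    ``profile`` selects the gene values: ``host`` uses the reference
    individual's bimodal modes, ``tumour`` the neoplastic profile (scaled
    high modes plus the planted differential flips).
    """
    genes = sg.truth["genes"]
    gene_vals = genes["host_value" if profile == "host" else "tumour_value"].to_numpy()
    pats = sg.truth["patterns"]
    c = REGIONAL_COEF
    gc_c = pats["gc"] - pats["gc"].mean()
    nb_frac = pats["nblock_count"] * 500.0 / sg.config.window_size
    nb_c = nb_frac - nb_frac.mean()
    delta_m = -c["c_gc"] * gc_c - c["c_n"] * nb_c + c["c_z"] * pats["z"]
    delta_h = -c["h_gc"] * gc_c + c["h_z"] * pats["z"]

    out = {}
    for contig, idx in sg.site_index.items():
        cls, win = idx["cls"], idx["window"]
        n = len(idx["pos"])
        mu_m = np.full(n, preset.intergenic_mc) + delta_m[win]
        mu_h = np.full(n, preset.intergenic_hmc) + delta_h[win]

        m_isl = cls == SITE_CLASS["cpg_island"]
        mu_m[m_isl] = preset.island_mc + delta_m[win[m_isl]]
        mu_h[m_isl] += preset.island_hmc_boost

        m_tan = cls == SITE_CLASS["tandem"]
        mu_m[m_tan] = preset.tandem_mc
        mu_h[m_tan] += preset.tandem_hmc_boost

        m_sat = cls == SITE_CLASS["satellite"]
        mu_m[m_sat] = preset.satellite_mc
        mu_h[m_sat] = preset.satellite_hmc

        m_gene = cls == SITE_CLASS["gene"]
        mu_m[m_gene] = gene_vals[idx["gene_idx"][m_gene]]
        mu_h[m_gene] = preset.intergenic_hmc + preset.gene_hmc_delta + delta_h[win[m_gene]]

        m_te = cls == SITE_CLASS["te"]
        fam_names = idx["te_family_names"]
        for code, fam in enumerate(fam_names):
            sel = m_te & (idx["te_family"] == code)
            mu_m[sel] = preset.te_mc[fam]

        np.clip(mu_m, 0.002, 0.98, out=mu_m)
        np.clip(mu_h, 0.002, 0.5, out=mu_h)
        out[contig] = (mu_m, mu_h)
    return out


def simulate_methylome(
    sg: SimulatedGenome,
    preset: LineagePreset,
    seed: int,
    sample_id: str,
    purity: float = 0.0,
    tumour_preset: LineagePreset | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate one sample's per-CpG call table.

    ``purity`` > 0 mixes the host profile of ``preset`` with the tumour
    profile of ``tumour_preset`` (tumour-cell fraction on the site means).
    Pure neoplastic lineages are simulated with ``purity=1`` and the
    lineage's own preset as ``tumour_preset``.

    Returns the call frame plus a per-sample truth dict (per-gene true
    methylated-CpG proportions and the effective site means) for the
    expression coupling and for oracle tests.
    """
    if purity > 0 and tumour_preset is None:
        raise ValueError("tumour_preset required when purity > 0")
    if preset.depth_lambda <= 0:
        raise ValueError("depth lambda must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202, _hash(sample_id)]))
    host_mu = site_means(sg, preset, "host")
    tum_mu = site_means(sg, tumour_preset, "tumour") if purity > 0 else None
    lam = preset.depth_lambda if tumour_preset is None else \
        (1 - purity) * preset.depth_lambda + purity * tumour_preset.depth_lambda

    frames = []
    gene_true_prop: dict[str, float] = {}
    genes = sg.truth["genes"]
    for contig, idx in sg.site_index.items():
        mu_m, mu_h = host_mu[contig]
        if tum_mu is not None:
            mu_m = (1 - purity) * mu_m + purity * tum_mu[contig][0]
            mu_h = (1 - purity) * mu_h + purity * tum_mu[contig][1]
        n = len(idx["pos"])
        conc_m, conc_h = preset.beta_conc_mc, preset.beta_conc_hmc
        level_m = rng.beta(mu_m * conc_m, (1 - mu_m) * conc_m)
        level_h = rng.beta(mu_h * conc_h, (1 - mu_h) * conc_h)
        # keep the joint site level feasible for the joint binomial draw
        level_h = np.minimum(level_h, 0.98 - level_m)
        np.clip(level_h, 1e-6, None, out=level_h)
        depth = rng.poisson(lam, size=n)
        keep = depth > 0
        k_m = rng.binomial(depth[keep], level_m[keep])
        rest = depth[keep] - k_m
        k_h = rng.binomial(rest, np.minimum(level_h[keep] / np.maximum(1 - level_m[keep], 1e-9), 1.0))
        frames.append(pd.DataFrame({
            "contig": contig,
            "pos": idx["pos"][keep],
            "mc_frac": k_m / depth[keep],
            "hmc_frac": k_h / depth[keep],
            "depth": depth[keep],
            "sample_id": sample_id,
        }))
        # per-gene true methylated-site proportions (threshold 0.5)
        gmask = idx["gene_idx"] >= 0
        if gmask.any():
            df = pd.DataFrame({"g": idx["gene_idx"][gmask],
                               "hot": (level_m[gmask] >= 0.5).astype(float)})
            for g, frac in df.groupby("g")["hot"].mean().items():
                gene_true_prop[genes.iloc[int(g)]["gene_id"]] = float(frac)

    calls = pd.concat(frames, ignore_index=True)
    sample_truth = {
        "sample_id": sample_id,
        "purity": purity,
        "gene_true_prop": pd.Series(gene_true_prop),
        "depth_lambda": lam,
    }
    return calls, sample_truth


def _hash(s: str) -> int:
    # platform-stable string hash for seeding (hash() is salted per process)
    return int(sum((i + 1) * ord(ch) for i, ch in enumerate(s)) % (2**31))


def simulate_per_read_calls(
    site_positions,
    site_levels,
    n_reads: int = 12,
    flip_rate: float = 0.03,
    seed: int = 0,
) -> pd.DataFrame:
    """Read-level methylation states at one locus.

    Each read reports every site's consensus state (level >= 0.5) flipped
    independently with ``flip_rate`` — the "consistent locus" regime in
    which reads mapping to the same locus agree at most sites.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    pos = np.asarray(site_positions)
    state = (np.asarray(site_levels, dtype=float) >= 0.5).astype(int)
    rows = []
    for r in range(n_reads):
        flips = rng.random(len(pos)) < flip_rate
        rows.append(pd.DataFrame({
            "read_id": f"read_{r}",
            "pos": pos,
            "state": np.where(flips, 1 - state, state),
        }))
    return pd.concat(rows, ignore_index=True)
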