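"""Lineage presets and the desk-scale genome configuration.

Each preset bundles the generator parameters for one lineage (healthy,
CedBTN1, CedBTN2): sequencing depth, regional 5mC/5hmC levels, the bimodal
gene-mode mixture, retroelement planting plans, insertion-callset truth
counts and the expression-coupling strength.  The headline levels
(intergenic baselines, gene-mode locations, hydroxymethylation baselines,
expression coupling) were fixed once with ``scripts/calibrate_presets.py``
so that each lineage's summary statistics land on the study's printed
values; the calibrated numbers are frozen here and are not free knobs.

The genome is desk-scale (2 contigs x 2.5 Mb, 100-kb windows).  All
percentage-type targets are scale-free, so miniaturisation preserves them;
per-window covariate patterns (GC, gene density, islands, tandem arrays,
N-blocks, a latent factor coupling 5mC and 5hmC) are fixed layout constants
shared by every preset and seed, which keeps genome-level means tight
across seeds while leaving plenty of between-window contrast for the
regression models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# genome configuration and fixed window-level layout patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeConfig:
    n_contigs: int = 2
    contig_length: int = 2_500_000
    window_size: int = 100_000
    n_diff_down: int = 94     # genes hypermethylated in host, low in tumour
    n_diff_up: int = 20       # genes methylated only in the tumour profile

    @property
    def n_windows(self) -> int:
        return self.n_contigs * (self.contig_length // self.window_size)

    @property
    def genome_size(self) -> int:
        return self.n_contigs * self.contig_length


_LAYOUT_SEED = 7_042_023  # layout constants; independent of user seeds


def layout_patterns(config: GenomeConfig) -> dict[str, np.ndarray]:
    """Fixed per-window covariate patterns (identical for every run/seed).

    The six patterns are rank-mapped onto QR-orthogonalised scores, so the
    window covariates are close to mutually orthogonal: each regression
    effect is then attributable to its own covariate instead of leaking
    into chance-correlated ones.
    """
    rng = np.random.default_rng(_LAYOUT_SEED)
    n = config.n_windows
    scores = rng.standard_normal((n, 6))
    scores -= scores.mean(axis=0)
    q, _ = np.linalg.qr(scores)
    ranks = np.argsort(np.argsort(q, axis=0), axis=0)

    def mapped(col, values):
        return np.sort(np.asarray(values, dtype=float))[ranks[:, col]]

    pats = {
        "gc": mapped(0, np.linspace(0.34, 0.48, n)),
        "gene_frac": mapped(1, np.linspace(0.10, 0.45, n)),
        "island_count": mapped(2, np.resize(np.arange(7), n)),
        "tandem_frac": mapped(3, np.linspace(0.0, 0.08, n)),
        "nblock_count": mapped(4, np.resize(np.arange(6), n)),
        "z": mapped(5, np.linspace(-1.0, 1.0, n)),
    }
    # one satellite array, in the least gene-dense window of the first contig
    first = config.contig_length // config.window_size
    pats["satellite_window"] = int(np.argmin(pats["gene_frac"][:first]))
    return pats


# regional-effect coefficients shared by all presets (see docs/methods.md)
REGIONAL_COEF = {
    "c_gc": 0.85,    # 5mC decrease per unit GC above the layout mean
    "c_n": 2.0,      # 5mC decrease per unit N-block fraction
    "c_z": 0.02,     # 5mC loading on the latent window factor
    "h_gc": 0.06,    # 5hmC decrease per unit GC
    "h_z": 0.012,    # 5hmC loading on the latent window factor
}


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TEPlantItem:
    family: str
    c_start: int            # consensus span planted
    c_end: int
    divergence: float       # private per-copy substitution rate
    shared_divergence: float = 0.0   # applied once to a common ancestor
    strand: str = "+"


@dataclass(frozen=True)
class InsertionPlan:
    # number of true (filter-surviving) insertions per family
    true_counts: dict
    # (fragment_length or "full"/"dimer", count) composition per family
    composition: dict
    decoys_per_reason: int = 2


@dataclass(frozen=True)
class LineagePreset:
    name: str
    depth_lambda: float
    # 5mC regional means (fractions)
    intergenic_mc: float
    island_mc: float
    tandem_mc: float
    satellite_mc: float
    te_mc: dict
    # gene-mode mixture (host scale for healthy; tumour profile scaled)
    gene_low_loc: float
    gene_low_sd: float
    gene_high_loc: float
    gene_high_sd: float
    p_high: float
    tumour_gene_scale: float
    # 5hmC model
    intergenic_hmc: float
    island_hmc_boost: float
    tandem_hmc_boost: float
    gene_hmc_delta: float
    satellite_hmc: float
    # noise
    beta_conc_mc: float
    beta_conc_hmc: float
    # expression coupling: log10 expression = alpha + beta * prop + eps
    expr_alpha: float
    expr_beta: float
    expr_sigma: float
    # planting plans
    te_plan: tuple
    insertion_plan: InsertionPlan | None
    # the printed values this preset is calibrated to reproduce (percent)
    targets: dict = field(default_factory=dict)


def _cl34_full(n, div, shared=0.0):
    return tuple(
        TEPlantItem("CedCL34", 0, 7500, div, shared, "+" if i % 3 else "-")
        for i in range(n)
    )


def _cl34_fragments(spans, div=0.05):
    return tuple(
        TEPlantItem("CedCL34", s, e, div) for s, e in spans
    )


# healthy CedCL24 plant: exactly 0.30% of the 5-Mb genome = 15,000 bases
_HEALTHY_CL24 = (
    TEPlantItem("CedCL24", 0, 6200, 0.02),
    TEPlantItem("CedCL24", 0, 6200, 0.02, strand="-"),
    TEPlantItem("CedCL24", 1000, 3600, 0.02),
)

_HEALTHY_TE_PLAN = (
    # six full-length low-copy elements sharing an old ancestor
    *_cl34_full(6, 0.01, shared=0.04),
    # sub-threshold fragments: found but not full-length
    *_cl34_fragments([(0, 1900), (1000, 3300), (2000, 5000),
                      (3000, 6800), (500, 4600), (4000, 7500)]),
    # decoys: below the match length / identity gates
    TEPlantItem("CedCL34", 100, 260, 0.05),
    TEPlantItem("CedCL34", 2000, 2400, 0.25),
    *_HEALTHY_CL24,
)

_CEDBTN1_TE_PLAN = (
    *_cl34_full(9, 0.01),
    *_cl34_fragments([(0, 2600), (2500, 5600), (1200, 4800)], div=0.015),
    TEPlantItem("CedCL24", 0, 6200, 0.02),
    TEPlantItem("CedCL24", 0, 6200, 0.02, strand="-"),
    TEPlantItem("CedCL24", 800, 4900, 0.02),
)

_CEDBTN2_TE_PLAN = (
    *_cl34_full(7, 0.015),
    *_cl34_fragments([(0, 3000), (3000, 7000)], div=0.02),
    TEPlantItem("CedCL24", 0, 6200, 0.02),
    TEPlantItem("CedCL24", 0, 6200, 0.02, strand="-"),
    TEPlantItem("CedCL24", 500, 5700, 0.02),
    TEPlantItem("CedCL24", 1500, 4200, 0.02),
)

# calibrated constants (output of scripts/calibrate_presets.py, frozen)
_CAL = {
    "healthy": {"b0": 0.1983, "h0": 0.0151, "high_loc": 0.6392,
                "low_loc": 0.0249, "alpha": 0.8, "beta": 1.45, "sigma": 1.311},
    "cedbtn1": {"b0": 0.1289, "h0": 0.0347, "high_loc": 0.6392,
                "low_loc": 0.0249, "alpha": 0.8, "beta": 1.15, "sigma": 0.618},
    "cedbtn2": {"b0": 0.1479, "h0": 0.0517, "high_loc": 0.6392,
                "low_loc": 0.0249, "alpha": 0.8, "beta": 1.50, "sigma": 0.636},
}


def _preset(name, cal, **kw) -> LineagePreset:
    base = dict(
        gene_low_loc=cal["low_loc"], gene_low_sd=0.008,
        gene_high_loc=cal["high_loc"], gene_high_sd=0.228, p_high=0.45,
        tumour_gene_scale=0.60,
        island_hmc_boost=0.10, tandem_hmc_boost=0.12, gene_hmc_delta=-0.018,
        satellite_hmc=0.003, satellite_mc=0.004,
        island_mc=0.55, tandem_mc=0.04,
        beta_conc_mc=12.0, beta_conc_hmc=30.0,
        intergenic_mc=cal["b0"], intergenic_hmc=cal["h0"],
        expr_alpha=cal["alpha"], expr_beta=cal["beta"], expr_sigma=cal["sigma"],
    )
    base.update(kw)
    return LineagePreset(name=name, **base)


PRESETS: dict[str, LineagePreset] = {
    "healthy": _preset(
        "healthy", _CAL["healthy"],
        depth_lambda=14.72,
        te_mc={"CedCL34": 0.1175, "CedCL24": 0.3214},
        te_plan=_HEALTHY_TE_PLAN,
        insertion_plan=InsertionPlan(true_counts={"CedCL34": 0, "CedCL24": 0},
                                     composition={}),
        targets={
            "window_mc_percent": 24.10,
            "window_hmc_percent": 2.83,
            "gene_low_mode_percent": 2.52,
            "gene_high_mode_percent": 61.66,
            "expression_r": 0.41,
            "cl34_full_length_copies": 6,
            "cl24_coverage_percent": 0.30,
        },
    ),
    "cedbtn1": _preset(
        "cedbtn1", _CAL["cedbtn1"],
        depth_lambda=7.54,
        island_mc=0.38,
        te_mc={"CedCL34": 0.3744, "CedCL24": 0.1958},
        te_plan=_CEDBTN1_TE_PLAN,
        insertion_plan=InsertionPlan(
            true_counts={"CedCL34": 60, "CedCL24": 13},
            composition={
                "CedCL34": (("fragment", 34), ("full", 16), ("dimer", 10)),
                "CedCL24": (("fragment", 7), ("full", 2), ("dimer", 4)),
            },
        ),
        targets={
            "window_mc_percent": 14.61,
            "window_hmc_percent": 4.60,
            "cl34_element_mc_percent": 37.44,
            "expression_r": 0.34,
            "cl34_insertions": 60,
        },
    ),
    "cedbtn2": _preset(
        "cedbtn2", _CAL["cedbtn2"],
        depth_lambda=13.02,
        island_mc=0.40,
        te_mc={"CedCL34": 0.1888, "CedCL24": 0.2096},
        te_plan=_CEDBTN2_TE_PLAN,
        insertion_plan=InsertionPlan(
            true_counts={"CedCL34": 54, "CedCL24": 31},
            composition={
                "CedCL34": (("fragment", 30), ("full", 14), ("dimer", 10)),
                "CedCL24": (("fragment", 20), ("full", 5), ("dimer", 6)),
            },
        ),
        targets={
            "window_mc_percent": 15.55,
            "window_hmc_percent": 6.29,
            "cl34_element_mc_percent": 18.88,
            "expression_r": 0.42,
            "cl34_insertions": 54,
        },
    ),
}


# ---------------------------------------------------------------------------
# cohort plan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSample:
    sample_id: str
    lineage: str           # healthy / CedBTN1
    tissue: str
    tumour_purity: float
    intensity: str


def cohort_plan() -> tuple[CohortSample, ...]:
    """The mixed-purity cohort: 3 healthy tissues, 3 infiltrated gills,
    2 pure neoplastic haemolymphs (all tumours of the CedBTN1 lineage)."""
    from . import classify_intensity

    samples = [
        ("healthy_foot_1", "healthy", "foot", 0.0),
        ("healthy_foot_2", "healthy", "foot", 0.0),
        ("healthy_siphon_1", "healthy", "siphon", 0.0),
        ("cedbtn1_gill_1", "CedBTN1", "gill", 0.35),
        ("cedbtn1_gill_2", "CedBTN1", "gill", 0.45),
        ("cedbtn1_gill_3", "CedBTN1", "gill", 0.55),
        ("cedbtn1_haemolymph_1", "CedBTN1", "haemolymph", 0.92),
        ("cedbtn1_haemolymph_2", "CedBTN1", "haemolymph", 0.96),
    ]
    return tuple(
        CohortSample(sid, lin, tis, pur,
                     "N0" if pur == 0 else "N3")
        for sid, lin, tis, pur in samples
    )
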