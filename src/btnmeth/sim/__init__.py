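"""Seeded synthetic-data generator for the whole pipeline.

Generates desk-scale genomes with annotation tracks, per-CpG 5mC/5hmC call
tables, expression count tables, structural-variant insertion callsets and
retroelement copy sets whose statistical structure matches the study design:
bimodal gene-body methylation, genome-wide tumour hypomethylation, 5hmC
enrichment on tandem repeats and CpG islands with a satellite modification
desert, methylation-coupled expression, depth-dependent binomial call noise,
and a mixed-purity cohort.  Named lineage presets are calibrated so the
headline summary statistics of each simulated lineage reproduce the study's
printed values.
"""

from .presets import PRESETS, GenomeConfig, LineagePreset, cohort_plan
from .genome import SimulatedGenome, simulate_genome
from .methylome import simulate_methylome, simulate_per_read_calls
from .expression import simulate_expression
from .insertions import simulate_insertion_callset
from .tecopies import simulate_te_copies
from .consensus import consensus_elements

__all__ = [
    "PRESETS", "GenomeConfig", "LineagePreset", "cohort_plan",
    "SimulatedGenome", "simulate_genome", "simulate_methylome",
    "simulate_per_read_calls", "simulate_expression",
    "simulate_insertion_callset", "simulate_te_copies",
    "consensus_elements", "classify_intensity",
]


def classify_intensity(tumour_cell_fraction: float) -> str:
    """Disseminated-neoplasia intensity class from the tumoral haemocyte fraction.

    N0: none; N1: (0, 0.15]; N2: (0.15, 0.75]; N3: (0.75, 1].  The class
    boundaries are taken inclusive-upper.
    """
    f = float(tumour_cell_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"tumour cell fraction {f} outside [0, 1]")
    if f == 0.0:
        return "N0"
    if f <= 0.15:
        return "N1"
    if f <= 0.75:
        return "N2"
    return "N3"
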