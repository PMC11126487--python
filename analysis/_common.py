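"""Shared plumbing for the numbered analysis drivers.

Every driver regenerates its inputs deterministically from ANALYSIS_SEED via
the library, so each script can be run on its own; `01_simulate_cohort.py`
additionally materialises the raw simulated files under scratch/ for
inspection.  Small result tables go to results/.
"""

from pathlib import Path

ANALYSIS_SEED = 1

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    return RESULTS, SCRATCH


def lineage_sim(name: str, seed: int = ANALYSIS_SEED):
    """Simulated genome + single-sample methylome for one lineage preset."""
    from btnmeth.sim import PRESETS, simulate_genome, simulate_methylome

    preset = PRESETS[name]
    sg = simulate_genome(preset, seed)
    purity = 0.0 if name == "healthy" else 1.0
    calls, truth = simulate_methylome(
        sg, PRESETS["healthy"] if purity else preset, seed, name,
        purity, preset if purity else None)
    return sg, calls, truth


def cohort_sims(seed: int = ANALYSIS_SEED):
    from btnmeth.sim import PRESETS, cohort_plan, simulate_genome, simulate_methylome

    sg = simulate_genome(PRESETS["healthy"], seed)
    calls_by = {}
    plan = cohort_plan()
    for s in plan:
        calls_by[s.sample_id], _ = simulate_methylome(
            sg, PRESETS["healthy"], seed, s.sample_id, s.tumour_purity,
            PRESETS["cedbtn1"] if s.tumour_purity else None)
    return sg, plan, calls_by
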