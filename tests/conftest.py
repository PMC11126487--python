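import numpy as np
import pandas as pd
import pytest

from btnmeth.sim import (PRESETS, cohort_plan, consensus_elements,
                         simulate_genome, simulate_methylome)

#: fixed seed for every simulation-backed test in the suite
TEST_SEED = 1234


@pytest.fixture(scope="session")
def healthy_sim():
    """Healthy-lineage genome + methylome, shared across the session."""
    sg = simulate_genome(PRESETS["healthy"], TEST_SEED)
    calls, truth = simulate_methylome(sg, PRESETS["healthy"], TEST_SEED, "healthy")
    return sg, calls, truth


@pytest.fixture(scope="session")
def cedbtn1_sim():
    sg = simulate_genome(PRESETS["cedbtn1"], TEST_SEED)
    calls, truth = simulate_methylome(sg, PRESETS["cedbtn1"], TEST_SEED, "cedbtn1",
                                      purity=1.0, tumour_preset=PRESETS["cedbtn1"])
    return sg, calls, truth


@pytest.fixture(scope="session")
def cedbtn2_sim():
    sg = simulate_genome(PRESETS["cedbtn2"], TEST_SEED)
    calls, truth = simulate_methylome(sg, PRESETS["cedbtn2"], TEST_SEED, "cedbtn2",
                                      purity=1.0, tumour_preset=PRESETS["cedbtn2"])
    return sg, calls, truth


@pytest.fixture(scope="session")
def cohort_matrix(healthy_sim):
    """Gene methylation matrix over the mixed-purity cohort."""
    from btnmeth.diffmeth import gene_matrix

    sg, _, _ = healthy_sim
    plan = cohort_plan()
    calls_by = {}
    for s in plan:
        c, _ = simulate_methylome(
            sg, PRESETS["healthy"], TEST_SEED, s.sample_id, s.tumour_purity,
            PRESETS["cedbtn1"] if s.tumour_purity > 0 else None)
        calls_by[s.sample_id] = c
    meta = pd.DataFrame(
        [{"sample_id": s.sample_id, "lineage": s.lineage, "tissue": s.tissue,
          "intensity": s.intensity} for s in plan]).set_index("sample_id")
    return gene_matrix(calls_by, sg.tracks["gene"], meta)


@pytest.fixture(scope="session")
def consensus():
    return consensus_elements()


@pytest.fixture()
def rng():
    return np.random.default_rng(TEST_SEED)
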