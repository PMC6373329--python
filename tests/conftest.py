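import numpy as np
import pytest

import netpet as nx
from netpet.kinetics import estimate_population_k2p, model_bp_table


@pytest.fixture(scope="session")
def paper_schedule():
    return nx.build_schedule(nx.PAPER_SCHEDULE_SPEC)


@pytest.fixture(scope="session")
def degenerate_cohort():
    """Noiseless cohort with zero inter-subject spread: every subject carries
    the template kinetics (k2' = 0.0322, registry BPND levels) exactly."""
    cfg = nx.CohortConfig(noise_alpha=0.0, k2p_sd=0.0, bp_jitter_sd=0.0, seed=1)
    return nx.generate_cohort(cfg)


@pytest.fixture(scope="session")
def degenerate_fits(degenerate_cohort):
    """Population k2' and the MRTM2/SRTM2 BP table for the degenerate cohort."""
    pop = estimate_population_k2p(degenerate_cohort)
    bp = model_bp_table(degenerate_cohort, pop.mean, pool="none")
    return pop, bp


@pytest.fixture(scope="session")
def noiseless_default_cohort():
    """Default study conditions with frame noise switched off (inter-subject
    k2' spread and BPND jitter retained)."""
    return nx.generate_cohort(nx.CohortConfig(noise_alpha=0.0, seed=1))


@pytest.fixture(scope="session")
def subject_tacs_90(degenerate_cohort):
    """First subject's TACs truncated to the 90-min modeling window."""
    subj = degenerate_cohort.subjects[0]
    return {name: tac.truncated(90.0) for name, tac in subj.tacs.items()}
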