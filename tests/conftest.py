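import pytest

from disambig import synthetic_cohort as sc
from disambig import task_engine as te
from disambig.task_engine import (
    PHASE_CONTROL_OTHER,
    PHASE_SELF_ONLY,
    PHASE_SELF_OTHER,
)

COHORT_N = 30
COHORT_SEED = 5


@pytest.fixture(scope="session")
def schedule():
    return te.generate_schedule(seed=3)


@pytest.fixture(scope="session")
def one_block_schedule():
    cfg = te.ScheduleConfig(n_blocks=1)
    return te.generate_schedule(cfg, seed=3)


@pytest.fixture(scope="session")
def participant_table(schedule):
    return sc.simulate_participant(schedule, sc.AgentParams(), seed=42)


@pytest.fixture(scope="session")
def cohort():
    """The 30-agent synthetic cohort shared by the behavioural tests."""
    manifest, tables = sc.simulate_cohort(COHORT_N, seed=COHORT_SEED)
    return manifest, tables


@pytest.fixture(scope="session")
def cohort_co_refits(cohort):
    """Control-Other refits of all three observer variants per participant."""
    _, tables = cohort
    return {pid: sc.refit_learners(tab) for pid, tab in tables.items()}


@pytest.fixture(scope="session")
def cohort_active_estimates(cohort):
    """Active-learner estimates for every phase (model-based analyses)."""
    _, tables = cohort
    phases = (PHASE_SELF_OTHER, PHASE_SELF_ONLY, PHASE_CONTROL_OTHER)
    return {
        pid: sc.refit_learners(tab, variants=("active",), phases=phases)
        for pid, tab in tables.items()
    }


def variant_tables(tables, co_refits, active_full, variant):
    """Trial tables with control ratings read from one observer variant."""
    out = {}
    for pid, tab in tables.items():
        est = active_full[pid] if variant == "active" else co_refits[pid]
        out[pid] = sc.as_model_table(tab, est, variant)
    return out
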