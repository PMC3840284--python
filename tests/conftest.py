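"""Shared fixtures: agents, short schedule configs, synthetic log builders."""

from __future__ import annotations

import numpy as np
import pytest

from aeforage import (
    AgentParams,
    ChamberGeometry,
    EnergyQuantities,
    ScheduleConfig,
    SessionLog,
    TrialRecord,
    make_agent,
)


@pytest.fixture
def geometry():
    return ChamberGeometry()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return ScheduleConfig(fr_requirement=15)


@pytest.fixture
def short_config():
    """Three-block sessions keep structural tests fast."""
    return ScheduleConfig(fr_requirement=15, trials_per_session=12)


@pytest.fixture
def always_ae():
    return make_agent("always-ae")


@pytest.fixture
def always_fr():
    return make_agent("always-fr")


@pytest.fixture
def alternating():
    return make_agent("alternating")


@pytest.fixture
def stationary():
    return make_agent("stationary")


def make_quantities(ire: float, irt: float = 1.0) -> EnergyQuantities:
    """EnergyQuantities with the requested IRE at the given IRT."""
    ird = float(np.sqrt(ire) * irt)
    return EnergyQuantities(ird=ird, irt=irt, ire=ire)


def make_ae_trial(
    ires,
    reinforced,
    trial_type="free",
    trial_index=0,
    block_index=0,
    requirement=0.03,
):
    """Synthetic AE TrialRecord carrying the given attempt IREs."""
    return TrialRecord(
        trial_index=trial_index,
        block_index=block_index,
        trial_type=trial_type,
        chosen_schedule="AE",
        peck_events=[],
        ire_attempts=[make_quantities(v) for v in ires],
        reinforced=reinforced,
        corrections_used=0 if trial_type == "free" else max(len(ires) - 1, 0),
        ae_requirement_at_trial=requirement,
    )


def make_fr_trial(trial_index=0, block_index=0, requirement=0.03, trial_type="free"):
    return TrialRecord(
        trial_index=trial_index,
        block_index=block_index,
        trial_type=trial_type,
        chosen_schedule="FR",
        peck_events=[],
        ire_attempts=[],
        reinforced=True,
        corrections_used=0,
        ae_requirement_at_trial=requirement,
    )


def make_session(trials, session_index=0, label="synthetic"):
    """Wrap synthetic trials in a SessionLog (summaries recomputed)."""
    means = [t.ae_requirement_at_trial for t in trials]
    mean_req = float(np.mean(means)) if means else 0.01
    return SessionLog(
        session_index=session_index,
        condition_label=label,
        trials=list(trials),
        mean_ae_requirement=mean_req,
        final_block_ae_requirement=means[-1] if means else 0.01,
        carryover_requirement=means[-1] if means else 0.01,
        rng_seed=0,
        ae_start=means[0] if means else 0.01,
    )
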