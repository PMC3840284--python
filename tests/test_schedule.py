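"""Schedule engine: trials, corrections, blocks, titration, conditions."""

import numpy as np
import pytest

from aeforage import (
    AEState,
    Clock,
    ConditionNotStableError,
    InvalidArgumentError,
    InvalidBehaviorError,
    ScheduleConfig,
    StateError,
    apply_ae_adjustment,
    make_agent,
    run_condition,
    run_session,
    run_trial,
    session_rng_seed,
)
from aeforage.agents import Agent, AgentParams
from aeforage.geometry import PeckEvent


def failing_agent():
    """Pecks with zero displacement: IRE = 0, never meets a requirement."""
    return make_agent("always-ae", peck_scatter="gaussian", scatter_sigma=0.0)


class OutsideAgent(Agent):
    """Misbehaving agent that pecks off the response surface."""

    def generate_peck_pair(self, ae_requirement, rng, t_first):
        from aeforage.agents import PeckPair

        return PeckPair(
            PeckEvent(0.5, 0.5, t_first), PeckEvent(0.5, 0.5, t_first + 0.2)
        )


class TestApplyAdjustment:
    @pytest.mark.parametrize(
        "choices, expected",
        [
            (("AE", "AE"), 0.031),
            (("FR", "FR"), 0.029),
            (("AE", "FR"), 0.030),
            (("FR", "AE"), 0.030),
        ],
    )
    def test_block_outcomes(self, choices, expected, default_config):
        state = AEState(requirement=0.030)
        new = apply_ae_adjustment(choices, state, default_config, block_index=3)
        assert new == pytest.approx(expected, abs=1e-12)
        assert state.requirement == new
        assert state.history == [(3, new)]

    def test_floor_clipping(self, default_config):
        state = AEState(requirement=0.001, floor=0.001)
        assert apply_ae_adjustment(("FR", "FR"), state, default_config) == 0.001

    def test_mid_block_call_rejected(self, default_config):
        with pytest.raises(StateError):
            apply_ae_adjustment(("AE",), AEState(requirement=0.03), default_config)
        with pytest.raises(InvalidArgumentError):
            apply_ae_adjustment(("AE", "left"), AEState(requirement=0.03), default_config)


class TestRunTrial:
    def test_forced_ae_failure_exhausts_five_corrections(self, default_config):
        """An always-failing agent uses the full correction allowance:
        six attempts (initial + five corrections), no reinforcer."""
        record = run_trial(
            failing_agent(),
            "forced-left",
            AEState(requirement=0.01),
            default_config,
            Clock(),
            np.random.default_rng(0),
        )
        assert record.reinforced is False
        assert record.corrections_used == 5
        assert len(record.ire_attempts) == 6
        assert len(record.peck_events) == 12

    def test_free_ae_failure_has_no_corrections(self, default_config):
        record = run_trial(
            failing_agent(),
            "free",
            AEState(requirement=0.01),
            default_config,
            Clock(),
            np.random.default_rng(0),
        )
        assert record.reinforced is False
        assert record.corrections_used == 0
        assert len(record.ire_attempts) == 1

    def test_fr_trial_reinforces_after_exact_count(self, always_fr, default_config):
        record = run_trial(
            always_fr,
            "free",
            AEState(requirement=0.01),
            default_config,
            Clock(),
            np.random.default_rng(1),
        )
        assert record.chosen_schedule == "FR"
        assert record.reinforced is True
        assert len(record.peck_events) == default_config.fr_requirement
        assert record.corrections_used == 0

    def test_zero_requirement_reinforces_any_movement(self, stationary, default_config):
        record = run_trial(
            stationary,
            "forced-left",
            AEState(requirement=0.0, floor=0.0),
            default_config,
            Clock(),
            np.random.default_rng(2),
        )
        assert record.reinforced is True
        assert len(record.ire_attempts) == 1

    def test_forced_right_runs_fr_schedule(self, always_ae, default_config):
        record = run_trial(
            always_ae,
            "forced-right",
            AEState(requirement=0.01),
            default_config,
            Clock(),
            np.random.default_rng(3),
        )
        assert record.chosen_schedule == "FR"

    def test_peck_outside_response_area_rejected(self, default_config):
        with pytest.raises(InvalidBehaviorError):
            run_trial(
                OutsideAgent(),
                "forced-left",
                AEState(requirement=0.01),
                default_config,
                Clock(),
                np.random.default_rng(0),
            )

    def test_clock_advances_through_reinforcer_and_iti(self, always_fr, default_config):
        clock = Clock()
        record = run_trial(
            always_fr, "free", AEState(requirement=0.01), default_config, clock,
            np.random.default_rng(4),
        )
        assert clock.t == record.end_time
        assert clock.t >= record.peck_events[-1].t + default_config.reinforcer_duration + default_config.iti


class TestRunSession:
    def test_default_session_structure(self, stationary, default_config):
        log = run_session(stationary, default_config, 0.010, 99)
        assert len(log.trials) == 60
        assert sum(t.trial_type == "free" for t in log.trials) == 30
        assert sum(t.trial_type != "free" for t in log.trials) == 30
        assert max(t.block_index for t in log.trials) == 14

    def test_each_block_has_one_forced_left_and_one_forced_right(
        self, stationary, default_config
    ):
        log = run_session(stationary, default_config, 0.010, 5)
        for b in range(15):
            types = [t.trial_type for t in log.trials if t.block_index == b]
            assert types.count("forced-left") == 1
            assert types.count("forced-right") == 1
            assert types.count("free") == 2

    def test_always_ae_titration_walkthrough(self, always_ae, default_config):
        """From 0.010 J the requirement climbs one step per block: the
        final block runs at 0.010 + 14*0.001 = 0.024 J."""
        log = run_session(always_ae, default_config, 0.010, 7)
        per_block = {}
        for t in log.trials:
            per_block.setdefault(t.block_index, t.ae_requirement_at_trial)
        expected = [round(0.010 + 0.001 * b, 12) for b in range(15)]
        assert [per_block[b] for b in range(15)] == pytest.approx(expected, abs=1e-12)
        assert log.final_block_ae_requirement == pytest.approx(0.024, abs=1e-12)
        assert log.carryover_requirement == pytest.approx(0.025, abs=1e-12)
        assert log.mean_ae_requirement == pytest.approx(0.017, abs=1e-12)

    def test_always_fr_titration_descends_to_floor(self, always_fr):
        config = ScheduleConfig(fr_requirement=15)
        log = run_session(always_fr, config, 0.005, 7)
        reqs = sorted({t.ae_requirement_at_trial for t in log.trials}, reverse=True)
        assert reqs[0] == pytest.approx(0.005)
        assert min(reqs) == pytest.approx(config.ae_floor)

    def test_requirement_changes_only_between_blocks_by_one_step(self, stationary):
        config = ScheduleConfig(fr_requirement=30)
        log = run_session(stationary, config, 0.030, 21)
        # constant within a block
        for b in range(15):
            reqs = {t.ae_requirement_at_trial for t in log.trials if t.block_index == b}
            assert len(reqs) == 1
        # between blocks: 0 or +/- one step
        per_block = [
            next(t.ae_requirement_at_trial for t in log.trials if t.block_index == b)
            for b in range(15)
        ]
        for prev, nxt in zip(per_block, per_block[1:]):
            assert round(abs(nxt - prev), 12) in (0.0, config.ae_step)

    def test_time_cap_truncates_session(self, stationary):
        config = ScheduleConfig(fr_requirement=15, session_time_cap=60.0)
        log = run_session(stationary, config, 0.010, 3)
        assert 0 < len(log.trials) < 60

    def test_zero_time_cap_yields_empty_session(self, stationary):
        config = ScheduleConfig(fr_requirement=15, session_time_cap=0.0)
        log = run_session(stationary, config, 0.010, 3)
        assert log.trials == []
        assert log.carryover_requirement == pytest.approx(0.010)

    def test_incomplete_final_block_contributes_no_adjustment(self, always_ae):
        # cap long enough for a few blocks but not all 15
        config = ScheduleConfig(fr_requirement=15, session_time_cap=200.0)
        log = run_session(always_ae, config, 0.010, 3)
        completed = len(log.trials) // config.block_size
        assert log.carryover_requirement == pytest.approx(
            0.010 + completed * config.ae_step, abs=1e-12
        )

    def test_reinforcers_never_exceed_trials(self, stationary, default_config):
        log = run_session(stationary, default_config, 0.010, 13)
        assert sum(t.reinforced for t in log.trials) <= len(log.trials)

    def test_ae_start_below_floor_rejected(self, stationary, default_config):
        with pytest.raises(InvalidArgumentError):
            run_session(stationary, default_config, 0.0001, 0)


class TestRunCondition:
    def test_immediately_stable_agent_stops_at_minimum(self, alternating):
        config = ScheduleConfig(fr_requirement=15)
        logs = run_condition(alternating, config, 0.010, 11, "FR15")
        assert len(logs) == config.min_sessions_per_condition == 18

    def test_carryover_between_sessions(self, stationary):
        config = ScheduleConfig(fr_requirement=30)
        logs = run_condition(stationary, config, 0.010, 19, max_sessions=60)
        for prev, nxt in zip(logs, logs[1:]):
            assert nxt.ae_start == pytest.approx(prev.carryover_requirement, abs=1e-12)

    def test_drifting_agent_hits_hard_cap(self, always_ae):
        """A monotone titration can never satisfy criterion 1."""
        config = ScheduleConfig(fr_requirement=15)
        with pytest.raises(ConditionNotStableError) as excinfo:
            run_condition(always_ae, config, 0.010, 23, max_sessions=20)
        assert len(excinfo.value.logs) == 20

    def test_deterministic_under_fixed_seed(self, default_config):
        a1 = make_agent("stationary")
        a2 = make_agent("stationary")
        logs1 = run_condition(a1, default_config, 0.010, 31, max_sessions=40)
        logs2 = run_condition(a2, default_config, 0.010, 31, max_sessions=40)
        assert logs1 == logs2


class TestScheduleConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"block_size": 3},
            {"trials_per_session": 50},
            {"ae_step": -0.001},
            {"fr_requirement": 0},
            {"iti": -1.0},
            {"trials_per_session": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidArgumentError):
            ScheduleConfig(**kwargs)

    def test_session_seed_derivation_stable(self):
        assert session_rng_seed(7, 0) == session_rng_seed(7, 0)
        assert session_rng_seed(7, 0) != session_rng_seed(7, 1)
        assert 0 <= session_rng_seed(7, 3) < 2**31
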