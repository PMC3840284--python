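"""Discrete-event engine for the adjusting-energy (AE) titration procedure.

A session is a sequence of trials organised in blocks (default 60 trials,
15 blocks of 4: two forced-choice trials — one per key, pseudorandom
order — followed by two free-choice trials), capped at 90 simulated
minutes.  Each trial offers a fixed-ratio (FR) alternative and an AE
alternative:

* **FR**: the subject pecks the response area ``fr_requirement`` times
  and is reinforced.
* **AE**: the subject pecks twice; the pair is reinforced iff its
  interresponse energy strictly exceeds the current AE requirement.
  On *forced* AE trials a failed attempt re-runs the AE schedule phase
  after the intertrial interval (a correction trial), at most five
  times; free-trial failures simply end the trial unreinforced.

The AE requirement titrates block-wise on the two free choices: both AE
-> +0.001 J, both FR -> -0.001 J (clipped at the floor), mixed ->
unchanged, and the final block's adjustment carries over into the next
session's starting requirement.  A condition runs a minimum of 18
sessions and ends at the first session where the stability criteria
(see :mod:`aeforage.analysis`) are met.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean

import numpy as np

from .agents import Agent
from .errors import (
    ConditionNotStableError,
    InvalidArgumentError,
    InvalidBehaviorError,
    StateError,
)
from .geometry import ChamberGeometry, EnergyQuantities, PeckEvent, compute_ire

__all__ = [
    "ScheduleConfig",
    "AEState",
    "TrialRecord",
    "SessionLog",
    "Clock",
    "run_trial",
    "apply_ae_adjustment",
    "run_session",
    "run_condition",
    "session_rng_seed",
]

#: decimal places used to snap titrated requirements so that repeated
#: +/- 0.001 J steps stay exactly representable in the logs
_REQ_DECIMALS = 12


@dataclass(frozen=True)
class ScheduleConfig:
    """Parameters of one experimental condition.

    Defaults are the standard arrangement: 60-trial sessions capped at
    90 min, 15 blocks of four trials (2 forced + 2 free), a 0.001-J
    adjusting step, 3-s ITI, 4-s reinforcer access, at most five
    correction trials, and an 18-session minimum per condition.
    """

    fr_requirement: int = 30
    ae_step: float = 0.001
    iti: float = 3.0
    max_correction_trials: int = 5
    trials_per_session: int = 60
    session_time_cap: float = 5400.0
    block_size: int = 4
    reinforcer_duration: float = 4.0
    min_sessions_per_condition: int = 18
    ae_floor: float = 0.001

    def __post_init__(self) -> None:
        for name in (
            "fr_requirement",
            "max_correction_trials",
            "trials_per_session",
            "block_size",
            "min_sessions_per_condition",
        ):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise InvalidArgumentError(f"{name} must be an integer")
            if value <= 0 and name != "max_correction_trials":
                raise InvalidArgumentError(f"{name} must be positive, got {value}")
        if self.max_correction_trials < 0:
            raise InvalidArgumentError("max_correction_trials must be >= 0")
        if self.block_size % 2 != 0:
            raise InvalidArgumentError("block_size must be even (half forced, half free)")
        if self.trials_per_session % self.block_size != 0:
            raise InvalidArgumentError(
                "trials_per_session must be divisible by block_size"
            )
        if self.ae_step < 0:
            raise InvalidArgumentError("ae_step must be >= 0")
        if self.iti < 0 or self.reinforcer_duration < 0:
            raise InvalidArgumentError("durations must be >= 0")
        if self.session_time_cap < 0:
            raise InvalidArgumentError("session_time_cap must be >= 0")
        if self.ae_floor < 0:
            raise InvalidArgumentError("ae_floor must be >= 0")

    @property
    def blocks_per_session(self) -> int:
        return self.trials_per_session // self.block_size


@dataclass
class AEState:
    """The titrated AE requirement and its within-session history.

    ``history`` records ``(block_index, requirement)`` after each
    completed block's adjustment; the requirement never drops below
    ``floor``.
    """

    requirement: float
    floor: float = 0.001
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.requirement < self.floor:
            raise InvalidArgumentError(
                f"requirement {self.requirement} below floor {self.floor}"
            )


@dataclass
class TrialRecord:
    """Complete outcome of one trial."""

    trial_index: int
    block_index: int
    trial_type: str  # "forced-left" | "forced-right" | "free"
    chosen_schedule: str  # "AE" | "FR"
    peck_events: list  # schedule-phase PeckEvents, in order
    ire_attempts: list  # EnergyQuantities, one per AE attempt (incl. corrections)
    reinforced: bool
    corrections_used: int
    ae_requirement_at_trial: float
    choice_time: float = 0.0
    start_time: float = 0.0
    end_time: float = 0.0


@dataclass
class SessionLog:
    """Ordered trial records of one session plus its summaries.

    ``final_block_ae_requirement`` is the requirement in effect during
    the last *completed* block; ``carryover_requirement`` is that value
    after the block's adjustment, and seeds the next session.
    """

    session_index: int
    condition_label: str
    trials: list
    mean_ae_requirement: float
    final_block_ae_requirement: float
    carryover_requirement: float
    rng_seed: int
    ae_start: float

    @property
    def session_mean(self) -> float:
        return self.mean_ae_requirement


class Clock:
    """Simulated session clock (seconds)."""

    __slots__ = ("t",)

    def __init__(self, t: float = 0.0) -> None:
        self.t = t

    def advance(self, dt: float) -> None:
        self.t += dt


# key assignment: left key (blue) = AE schedule, right key (red) = FR
_FORCED_SCHEDULE = {"forced-left": "AE", "forced-right": "FR"}


def _check_inside(event: PeckEvent, geometry: ChamberGeometry) -> None:
    if not geometry.contains(event.x, event.y):
        raise InvalidBehaviorError(
            f"peck at ({event.x:.4f}, {event.y:.4f}) lies outside the "
            f"response area (radius {geometry.radius} m)"
        )


def run_trial(
    agent: Agent,
    trial_type: str,
    ae_state: AEState,
    config: ScheduleConfig,
    clock: Clock,
    rng: np.random.Generator,
    trial_index: int = 0,
    block_index: int = 0,
) -> TrialRecord:
    """Run one trial and advance the simulated clock through it.

    The choice phase resolves the schedule (forced trials present a
    single key; free trials query the agent), the schedule phase runs FR
    or AE (with corrections on forced AE failures), and reinforcer and
    ITI durations are consumed before the record is returned.
    """
    if trial_type not in ("forced-left", "forced-right", "free"):
        raise InvalidArgumentError(f"unknown trial_type {trial_type!r}")
    geometry = agent.geometry
    requirement = ae_state.requirement
    start_time = clock.t

    # --- choice phase ---
    clock.advance(agent.choice_latency(rng))
    choice_time = clock.t
    if trial_type == "free":
        chosen = agent.choose(config.fr_requirement, requirement, rng)
        if chosen not in ("AE", "FR"):
            raise InvalidBehaviorError(f"agent returned invalid choice {chosen!r}")
    else:
        chosen = _FORCED_SCHEDULE[trial_type]

    pecks: list[PeckEvent] = []
    attempts: list[EnergyQuantities] = []
    corrections = 0
    reinforced = False

    if chosen == "FR":
        fr_pecks = agent.generate_fr_pecks(
            config.fr_requirement, rng, clock.t + agent.choice_latency(rng)
        )
        for ev in fr_pecks:
            _check_inside(ev, geometry)
        pecks.extend(fr_pecks)
        clock.t = fr_pecks[-1].t
        reinforced = True
    else:  # AE schedule phase, with corrections on forced trials
        allow_corrections = trial_type != "free"
        while True:
            pair = agent.generate_peck_pair(
                requirement, rng, clock.t + agent.choice_latency(rng)
            )
            _check_inside(pair.first, geometry)
            _check_inside(pair.second, geometry)
            pecks.extend((pair.first, pair.second))
            clock.t = pair.second.t
            quantities = compute_ire(pair.first, pair.second)
            attempts.append(quantities)
            if quantities.ire > requirement:  # strict: equality fails
                reinforced = True
                break
            if allow_corrections and corrections < config.max_correction_trials:
                corrections += 1
                clock.advance(config.iti)  # ITI precedes each correction run
                continue
            break

    if reinforced:
        clock.advance(config.reinforcer_duration)
    clock.advance(config.iti)

    return TrialRecord(
        trial_index=trial_index,
        block_index=block_index,
        trial_type=trial_type,
        chosen_schedule=chosen,
        peck_events=pecks,
        ire_attempts=attempts,
        reinforced=reinforced,
        corrections_used=corrections,
        ae_requirement_at_trial=requirement,
        choice_time=choice_time,
        start_time=start_time,
        end_time=clock.t,
    )


def apply_ae_adjustment(
    free_choices,
    ae_state: AEState,
    config: ScheduleConfig,
    block_index: int = 0,
) -> float:
    """Titrate the AE requirement from one completed block's free choices.

    Both choices AE -> requirement += ae_step; both FR -> -= ae_step,
    clipped at the floor; one of each -> unchanged.  Appends the
    post-adjustment value to the state's history and returns it.
    """
    choices = tuple(free_choices)
    if len(choices) != 2:
        raise StateError(
            f"adjustment requires exactly two free-choice outcomes from a "
            f"completed block, got {len(choices)}"
        )
    for c in choices:
        if c not in ("AE", "FR"):
            raise InvalidArgumentError(f"invalid choice {c!r}")
    req = ae_state.requirement
    if choices == ("AE", "AE"):
        req += config.ae_step
    elif choices == ("FR", "FR"):
        req = max(ae_state.floor, req - config.ae_step)
    req = round(req, _REQ_DECIMALS)
    ae_state.requirement = req
    ae_state.history.append((block_index, req))
    return req


def run_session(
    agent: Agent,
    config: ScheduleConfig,
    ae_start: float,
    seed,
    session_index: int = 0,
    condition_label: str = "",
) -> SessionLog:
    """Run one session: blocks of forced/forced/free/free trials.

    The session ends after ``trials_per_session`` trials or at the time
    cap, whichever comes first (the cap is checked at trial boundaries).
    The adjustment after each completed block takes effect from the next
    block; an incomplete final block contributes no adjustment.
    """
    if ae_start < config.ae_floor:
        raise InvalidArgumentError(
            f"ae_start {ae_start} below requirement floor {config.ae_floor}"
        )
    rng = np.random.default_rng(seed)
    rng_seed = int(seed) if isinstance(seed, (int, np.integer)) else -1
    ae_state = AEState(requirement=round(ae_start, _REQ_DECIMALS), floor=config.ae_floor)
    clock = Clock()
    trials: list[TrialRecord] = []
    final_block_requirement = ae_state.requirement
    carryover = ae_state.requirement
    n_forced = config.block_size // 2
    trial_index = 0
    capped = False

    for block_index in range(config.blocks_per_session):
        block_requirement = ae_state.requirement
        # pseudorandom forced order: each left/right pair shuffled
        forced_types: list[str] = []
        for _ in range(n_forced // 2):
            pair = ["forced-left", "forced-right"]
            rng.shuffle(pair)
            forced_types.extend(pair)
        if n_forced % 2:  # odd half-block: a single coin-flip forced trial
            forced_types.append(
                "forced-left" if rng.random() < 0.5 else "forced-right"
            )
        plan = forced_types + ["free"] * (config.block_size - n_forced)

        block_trials: list[TrialRecord] = []
        for trial_type in plan:
            if clock.t >= config.session_time_cap:
                capped = True
                break
            record = run_trial(
                agent,
                trial_type,
                ae_state,
                config,
                clock,
                rng,
                trial_index=trial_index,
                block_index=block_index,
            )
            block_trials.append(record)
            trials.append(record)
            trial_index += 1
        if capped and len(block_trials) < config.block_size:
            break  # incomplete block: no adjustment
        free_choices = [
            t.chosen_schedule for t in block_trials if t.trial_type == "free"
        ]
        apply_ae_adjustment(free_choices[:2], ae_state, config, block_index)
        final_block_requirement = block_requirement
        carryover = ae_state.requirement
        if capped:
            break

    mean_requirement = (
        fmean(t.ae_requirement_at_trial for t in trials) if trials else ae_start
    )
    return SessionLog(
        session_index=session_index,
        condition_label=condition_label,
        trials=trials,
        mean_ae_requirement=mean_requirement,
        final_block_ae_requirement=final_block_requirement,
        carryover_requirement=carryover,
        rng_seed=rng_seed,
        ae_start=round(ae_start, _REQ_DECIMALS),
    )


def session_rng_seed(master_seed: int, session_index: int) -> int:
    """Derive one session's RNG seed from (master seed, session index).

    Sessions get independent streams, so a condition's sessions are
    reproducible individually and insertion-order independent.
    """
    ss = np.random.SeedSequence([int(master_seed), int(session_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_condition(
    agent: Agent,
    config: ScheduleConfig,
    ae_start: float,
    seed: int,
    condition_label: str = "",
    max_sessions: int = 200,
    trend_method: str = "ttest",
) -> list[SessionLog]:
    """Run sessions until the stability criteria are met.

    The starting requirement of each session is the previous session's
    final-block requirement after its adjustment (cross-session
    carryover).  Stability is assessed from session-mean requirements
    once ``min_sessions_per_condition`` sessions have run; the condition
    ends at the first session where all three criteria pass.

    Raises
    ------
    ConditionNotStableError
        If ``max_sessions`` sessions elapse without stability; the
        partial logs ride on the exception.
    """
    from .analysis import stability_check  # local import, avoids cycle

    logs: list[SessionLog] = []
    start = round(ae_start, _REQ_DECIMALS)
    for session_index in range(max_sessions):
        log = run_session(
            agent,
            config,
            start,
            session_rng_seed(seed, session_index),
            session_index=session_index,
            condition_label=condition_label,
        )
        logs.append(log)
        start = max(log.carryover_requirement, config.ae_floor)
        if len(logs) >= max(config.min_sessions_per_condition, 12):
            means = [s.mean_ae_requirement for s in logs]
            report = stability_check(
                means,
                config.min_sessions_per_condition,
                trend_method=trend_method,
            )
            if report.overall_pass:
                return logs
    raise ConditionNotStableError(
        f"condition {condition_label!r} not stable after {max_sessions} sessions",
        logs,
    )
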