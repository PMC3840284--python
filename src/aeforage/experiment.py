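"""Whole-experiment driver: an ordered series of FR conditions.

Runs each FR condition to stability with the configured agent, carrying
the titrated AE requirement over from the end of one condition into the
start of the next (the same continuity rule the schedule applies between
sessions), labels conditions as belonging to the ascending or descending
series, and condenses the logs into per-condition summaries and
cross-condition statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .analysis import ConditionSummary, CrossConditionStats, condition_summaries, summarize_condition
from .config import ExperimentConfig
from .schedule import run_condition

__all__ = ["ConditionResult", "ExperimentResult", "series_labels", "run_experiment"]


@dataclass
class ConditionResult:
    """One condition's logs plus identifying labels."""

    index: int
    fr_requirement: int
    series_label: str
    condition_label: str
    logs: list
    summary: ConditionSummary


@dataclass
class ExperimentResult:
    """All condition results plus the cross-condition table and stats."""

    conditions: list
    table: "object"  # pandas DataFrame
    stats: CrossConditionStats


def series_labels(conditions) -> list[str]:
    """Ascending/descending tag per condition in presentation order.

    Conditions up to and including the first occurrence of the largest
    FR requirement belong to the ascending series; the rest descend.
    """
    conditions = list(conditions)
    peak = conditions.index(max(conditions))
    return ["ascending" if i <= peak else "descending" for i in range(len(conditions))]


def condition_seed(master_seed: int, condition_index: int) -> int:
    """Independent per-condition seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), 10_000 + int(condition_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run every condition of the configured experiment to stability."""
    agent = cfg.build_agent()
    labels = series_labels(cfg.conditions)
    ae_start = cfg.ae_start
    results: list[ConditionResult] = []
    for i, fr in enumerate(cfg.conditions):
        schedule = dataclasses.replace(cfg.schedule, fr_requirement=fr)
        label = f"c{i + 1:02d}-FR{fr}-{labels[i][:3]}"
        logs = run_condition(
            agent,
            schedule,
            ae_start,
            condition_seed(cfg.seed, i),
            condition_label=label,
            max_sessions=cfg.max_sessions,
            trend_method=cfg.trend_method,
        )
        summary = summarize_condition(
            fr, logs, series_label=labels[i], condition_label=label
        )
        results.append(
            ConditionResult(
                index=i,
                fr_requirement=fr,
                series_label=labels[i],
                condition_label=label,
                logs=logs,
                summary=summary,
            )
        )
        # requirement continuity into the next condition
        ae_start = max(logs[-1].carryover_requirement, cfg.schedule.ae_floor)
    _, table, stats = condition_summaries([r.summary for r in results])
    return ExperimentResult(conditions=results, table=table, stats=stats)
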