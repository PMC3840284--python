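"""Analytics over session logs: stability, indifference points, IRE, E/RFT.

A condition's titrated AE requirement is judged stable from the series
of session means by three criteria: (1) neither the condition-wide
maximum nor minimum session mean occurs in the last six sessions,
(2) the last six session means show no systematic trend, and (3) the
last-six mean differs from the preceding-six mean by at most 7.5 %.

The indifference point of a condition — the AE requirement at which the
subject is equally likely to take either alternative — is estimated as
the mean AE requirement over the last six sessions.  The total energy
per reinforcement (E/RFT) sums the IREs of every free-choice AE attempt
emitted to earn one reinforcer, failed attempts included, and averages
over reinforcers; a condition with no reinforcers at all reports its
total IRE instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidArgumentError, UndefinedStatisticError

__all__ = [
    "StabilityReport",
    "ConditionSummary",
    "CrossConditionStats",
    "stability_check",
    "indifference_point",
    "e_per_rft",
    "collect_ire_samples",
    "summarize_condition",
    "condition_summaries",
]

STABILITY_PERCENT_LIMIT = 7.5  # criterion-3 window-difference bound, percent
TREND_ALPHA = 0.05  # criterion-2 slope-test significance level
STABILITY_WINDOW = 6  # sessions per comparison window


@dataclass(frozen=True)
class StabilityReport:
    """Outcome of the three stability criteria on a session-mean series."""

    criterion1_pass: bool
    criterion2_pass: bool
    criterion3_pass: bool
    last6_mean: float
    prev6_mean: float
    percent_diff: float
    trend_slope: float
    trend_pvalue: float

    @property
    def overall_pass(self) -> bool:
        return self.criterion1_pass and self.criterion2_pass and self.criterion3_pass


@dataclass
class ConditionSummary:
    """Per-condition analytics over the last six sessions."""

    fr_requirement: int
    indifference_point: float
    mean_ire: float
    ire_samples: list = field(default_factory=list)
    e_per_rft: float = float("nan")
    n_reinforcers: int = 0
    series_label: str = ""
    condition_label: str = ""
    n_sessions: int = 0


@dataclass
class CrossConditionStats:
    """Cross-condition association statistics (E/RFT vs. requirement)."""

    pearson_r: Optional[float]
    pearson_p: Optional[float]
    friedman_chi2: Optional[float]
    friedman_p: Optional[float]
    friedman_df: Optional[int]


def stability_check(
    session_means: Sequence[float],
    min_sessions: int = 18,
    trend_method: str = "ttest",
) -> StabilityReport:
    """Evaluate the three stability criteria on a session-mean series.

    Parameters
    ----------
    session_means : sequence of float
        Mean AE requirement per session, in session order; at least 12
        values are required (two six-session windows).
    min_sessions : int
        Minimum condition length; callers normally do not invoke the
        check before this many sessions have run.
    trend_method : {"ttest", "monotone"}
        Criterion-2 operationalisation.  ``"ttest"`` (default) fits a
        least-squares slope to the last six means and requires its
        two-sided t-test to be non-significant at alpha = 0.05;
        ``"monotone"`` instead fails when the last six means are
        strictly monotone.

    Notes
    -----
    Criterion 1 breaks ties toward failure — a session mean in the last
    six that *equals* the condition-wide extreme fails — except for the
    exactly-constant series, where every value is both maximum and
    minimum: perfect stability passes.
    """
    means = [float(m) for m in session_means]
    if len(means) < 2 * STABILITY_WINDOW:
        raise InsufficientDataError(
            f"stability needs at least {2 * STABILITY_WINDOW} session means, "
            f"got {len(means)}"
        )
    if trend_method not in ("ttest", "monotone"):
        raise InvalidArgumentError(f"unknown trend_method {trend_method!r}")

    last6 = means[-STABILITY_WINDOW:]
    prev6 = means[-2 * STABILITY_WINDOW : -STABILITY_WINDOW]

    # criterion 1: extremes excluded from the last six (ties fail), with a
    # carve-out for the exactly-constant series
    overall_max, overall_min = max(means), min(means)
    if overall_max == overall_min:
        criterion1 = True
    else:
        criterion1 = all(m != overall_max and m != overall_min for m in last6)

    # criterion 2: no systematic trend over the last six
    diffs = np.diff(last6)
    if np.ptp(last6) == 0:
        slope, pvalue = 0.0, 1.0
        criterion2 = True
    elif trend_method == "ttest":
        fit = stats.linregress(np.arange(STABILITY_WINDOW), last6)
        slope, pvalue = float(fit.slope), float(fit.pvalue)
        criterion2 = pvalue >= TREND_ALPHA
    else:
        fit = stats.linregress(np.arange(STABILITY_WINDOW), last6)
        slope, pvalue = float(fit.slope), float("nan")
        criterion2 = not (np.all(diffs > 0) or np.all(diffs < 0))

    # criterion 3: window means within 7.5 % of each other
    last6_mean = fmean(last6)
    prev6_mean = fmean(prev6)
    if prev6_mean == 0:
        percent_diff = 0.0 if last6_mean == 0 else float("inf")
    else:
        percent_diff = 100.0 * abs(last6_mean - prev6_mean) / abs(prev6_mean)
    # tolerance guards the exact-boundary case against float rounding
    criterion3 = percent_diff <= STABILITY_PERCENT_LIMIT + 1e-9

    return StabilityReport(
        criterion1_pass=bool(criterion1),
        criterion2_pass=bool(criterion2),
        criterion3_pass=bool(criterion3),
        last6_mean=last6_mean,
        prev6_mean=prev6_mean,
        percent_diff=percent_diff,
        trend_slope=slope,
        trend_pvalue=pvalue,
    )


def indifference_point(session_means: Sequence[float]) -> float:
    """Mean AE requirement over the last six sessions."""
    means = [float(m) for m in session_means]
    if len(means) < STABILITY_WINDOW:
        raise InsufficientDataError(
            f"indifference point needs {STABILITY_WINDOW} session means, "
            f"got {len(means)}"
        )
    return fmean(means[-STABILITY_WINDOW:])


def _free_ae_trials(session):
    return [
        t
        for t in session.trials
        if t.trial_type == "free" and t.chosen_schedule == "AE"
    ]


def e_per_rft(sessions) -> tuple[float, int]:
    """Total energy per reinforcement over free-choice AE trials.

    Within each session, consecutive free-choice AE trials form runs
    terminated by a reinforced trial; a run's energy is the sum of the
    IREs of *all* its attempts, failed ones included.  E/RFT is the mean
    run energy over reinforcers.  Runs never span session boundaries;
    trailing failures with no terminating reinforcer in their session do
    not enter a run.  If the sessions contain no reinforced free-choice
    AE trial at all, E/RFT falls back to the total IRE of every attempt.

    Parameters
    ----------
    sessions : iterable of SessionLog
        Normally the last six sessions of a condition.

    Returns
    -------
    (e_per_rft, n_reinforcers)

    Raises
    ------
    UndefinedStatisticError
        If the sessions contain no free-choice AE trials.
    """
    run_totals: list[float] = []
    grand_total = 0.0
    n_trials = 0
    for session in sessions:
        accumulated = 0.0
        for trial in _free_ae_trials(session):
            n_trials += 1
            trial_energy = sum(q.ire for q in trial.ire_attempts)
            grand_total += trial_energy
            accumulated += trial_energy
            if trial.reinforced:
                run_totals.append(accumulated)
                accumulated = 0.0
        # trailing failures at session end: no terminating reinforcer
    if n_trials == 0:
        raise UndefinedStatisticError(
            "E/RFT undefined: no free-choice AE trials in these sessions"
        )
    if not run_totals:
        return grand_total, 0
    return fmean(run_totals), len(run_totals)


def collect_ire_samples(sessions) -> list[float]:
    """IREs of every free-choice AE attempt in the given sessions."""
    return [
        q.ire
        for session in sessions
        for trial in _free_ae_trials(session)
        for q in trial.ire_attempts
    ]


def summarize_condition(
    fr_requirement: int,
    logs,
    series_label: str = "",
    condition_label: str = "",
    window: int = STABILITY_WINDOW,
) -> ConditionSummary:
    """Condense one condition's logs into its last-``window``-session summary."""
    logs = list(logs)
    means = [s.mean_ae_requirement for s in logs]
    point = indifference_point(means)
    last = logs[-window:]
    samples = collect_ire_samples(last)
    try:
        erft, n_rft = e_per_rft(last)
    except UndefinedStatisticError:
        erft, n_rft = float("nan"), 0
    return ConditionSummary(
        fr_requirement=int(fr_requirement),
        indifference_point=point,
        mean_ire=fmean(samples) if samples else float("nan"),
        ire_samples=samples,
        e_per_rft=erft,
        n_reinforcers=n_rft,
        series_label=series_label,
        condition_label=condition_label,
        n_sessions=len(logs),
    )


def condition_summaries(
    conditions,
) -> tuple[list[ConditionSummary], pd.DataFrame, CrossConditionStats]:
    """Summaries plus cross-condition statistics for a whole experiment.

    Parameters
    ----------
    conditions : sequence
        Either pre-built :class:`ConditionSummary` objects or tuples
        ``(fr_requirement, logs[, series_label[, condition_label]])``.

    Returns
    -------
    (summaries, table, stats) where ``table`` is one row per condition
    (FR requirement, indifference point, mean IRE, E/RFT, reinforcer
    count, series) and ``stats`` carries the Pearson correlation of
    E/RFT with the AE requirement and, when at least three FR levels
    have two or more replicates each, a Friedman test of the FR effect
    on the indifference point.  With fewer than two conditions the
    correlation is reported as absent (None).
    """
    summaries: list[ConditionSummary] = []
    for item in conditions:
        if isinstance(item, ConditionSummary):
            summaries.append(item)
        else:
            summaries.append(summarize_condition(*item))

    table = pd.DataFrame(
        {
            "fr_requirement": [s.fr_requirement for s in summaries],
            "indifference_point": [s.indifference_point for s in summaries],
            "mean_ire": [s.mean_ire for s in summaries],
            "e_per_rft": [s.e_per_rft for s in summaries],
            "n_reinforcers": [s.n_reinforcers for s in summaries],
            "series": [s.series_label for s in summaries],
            "condition": [s.condition_label for s in summaries],
        }
    )

    # Pearson correlation of E/RFT with the titrated requirement
    pearson_r = pearson_p = None
    valid = table.dropna(subset=["e_per_rft", "indifference_point"])
    if len(valid) >= 2 and valid["indifference_point"].nunique() > 1:
        r, p = stats.pearsonr(valid["indifference_point"], valid["e_per_rft"])
        pearson_r, pearson_p = float(r), float(p)

    # Friedman test of the FR-requirement effect on indifference points,
    # replicates (e.g. ascending/descending visits) as blocks
    friedman_chi2 = friedman_p = friedman_df = None
    groups = {
        fr: grp["indifference_point"].tolist()
        for fr, grp in table.groupby("fr_requirement")
    }
    if len(groups) >= 3:
        depth = min(len(v) for v in groups.values())
        if depth >= 2:
            trimmed = [groups[fr][:depth] for fr in sorted(groups)]
            chi2, p = stats.friedmanchisquare(*trimmed)
            friedman_chi2, friedman_p = float(chi2), float(p)
            friedman_df = len(groups) - 1

    cross = CrossConditionStats(
        pearson_r=pearson_r,
        pearson_p=pearson_p,
        friedman_chi2=friedman_chi2,
        friedman_p=friedman_p,
        friedman_df=friedman_df,
    )
    return summaries, table, cross
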