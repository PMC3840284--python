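"""Event-log serialization: plain CSV, lossless round-trip.

One file holds one or more sessions as a flat stream of events (one row
per trial-start, choice, peck, reinforcer, ITI and trial-end), preceded
by a single ``#``-prefixed header line that stamps the schema version
and carries the per-session summaries as JSON.  Floats are written with
``repr`` so a read-back reconstructs every trial record exactly
(bit-identical integers and flags, floats to full precision); IRE
attempts are recomputed from the peck rows on read.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

from .errors import LogParseError, LogVersionError
from .geometry import PeckEvent, compute_ire
from .schedule import SessionLog, TrialRecord

__all__ = ["write_logs", "read_logs", "LOG_FORMAT_VERSION"]

LOG_FORMAT_VERSION = 1
_MAGIC = "# aeforage-log"

_COLUMNS = [
    "session",
    "block",
    "trial",
    "trial_type",
    "event_kind",
    "x",
    "y",
    "t",
    "ae_requirement",
    "reinforced",
]


def _fmt(value: float) -> str:
    return repr(float(value))


def _session_meta(session: SessionLog) -> dict:
    return {
        "session_index": session.session_index,
        "condition_label": session.condition_label,
        "rng_seed": session.rng_seed,
        "ae_start": session.ae_start,
        "mean_ae_requirement": session.mean_ae_requirement,
        "final_block_ae_requirement": session.final_block_ae_requirement,
        "carryover_requirement": session.carryover_requirement,
        "n_trials": len(session.trials),
    }


def write_logs(sessions, path, metadata: dict | None = None) -> None:
    """Write sessions to one CSV event-log file.

    ``metadata`` (optional, JSON-serializable) is stored alongside the
    per-session summaries in the header line; ``read_logs`` returns it
    untouched.
    """
    sessions = list(sessions)
    path = Path(path)
    header = {
        "sessions": [_session_meta(s) for s in sessions],
        "metadata": metadata or {},
    }
    with path.open("w", newline="") as fh:
        fh.write(f"{_MAGIC} v{LOG_FORMAT_VERSION} {json.dumps(header)}\n")
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for session in sessions:
            for trial in session.trials:
                base = [
                    session.session_index,
                    trial.block_index,
                    trial.trial_index,
                    trial.trial_type,
                ]
                tail = [_fmt(trial.ae_requirement_at_trial), int(trial.reinforced)]

                def row(kind, x="", y="", t=0.0):
                    writer.writerow(base + [kind, x, y, _fmt(t)] + tail)

                row("trial-start", t=trial.start_time)
                row(f"choice-{trial.chosen_schedule}", t=trial.choice_time)
                for ev in trial.peck_events:
                    row("peck", _fmt(ev.x), _fmt(ev.y), ev.t)
                if trial.reinforced:
                    row("reinforcer", t=trial.peck_events[-1].t)
                row("trial-end", t=trial.end_time)


def _rebuild_trial(session_idx: int, rows: list, lineno_of: dict) -> TrialRecord:
    first = rows[0]
    trial_index = first["trial"]
    block_index = first["block"]
    trial_type = first["trial_type"]
    requirement = first["ae_requirement"]
    reinforced = first["reinforced"]

    chosen = None
    pecks: list[PeckEvent] = []
    start_time = end_time = choice_time = 0.0
    for r in rows:
        kind = r["event_kind"]
        if kind == "trial-start":
            start_time = r["t"]
        elif kind.startswith("choice-"):
            chosen = kind.split("-", 1)[1]
            choice_time = r["t"]
        elif kind == "peck":
            pecks.append(PeckEvent(r["x"], r["y"], r["t"]))
        elif kind == "trial-end":
            end_time = r["t"]
        elif kind == "reinforcer":
            pass
        else:
            raise LogParseError(
                f"line {r['lineno']}: unknown event kind {kind!r}"
            )
    if chosen not in ("AE", "FR"):
        raise LogParseError(
            f"line {lineno_of[trial_index]}: trial {trial_index} of session "
            f"{session_idx} has no choice event"
        )

    attempts = []
    if chosen == "AE":
        if len(pecks) % 2 != 0:
            raise LogParseError(
                f"line {lineno_of[trial_index]}: AE trial {trial_index} has an "
                f"odd number of pecks ({len(pecks)})"
            )
        for i in range(0, len(pecks), 2):
            attempts.append(compute_ire(pecks[i], pecks[i + 1]))
    corrections = (
        len(attempts) - 1 if chosen == "AE" and trial_type != "free" and attempts else 0
    )
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
        end_time=end_time,
    )


def read_logs(path) -> tuple[list, dict]:
    """Read an event-log file back into ``(sessions, metadata)``.

    Reconstructs every :class:`~aeforage.schedule.TrialRecord` from the
    event rows (IREs recomputed from the stored peck coordinates) and
    the session summaries from the header line.

    Raises
    ------
    LogVersionError
        If the file stamps a schema version this reader does not know.
    LogParseError
        On any malformed line; the message carries the line number.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith(_MAGIC):
            raise LogParseError(f"line 1: not an aeforage log file: {path}")
        rest = first[len(_MAGIC) :].strip()
        version_tag, _, payload = rest.partition(" ")
        if version_tag != f"v{LOG_FORMAT_VERSION}":
            raise LogVersionError(
                f"line 1: unsupported log version {version_tag!r} "
                f"(this reader knows v{LOG_FORMAT_VERSION})"
            )
        try:
            header = json.loads(payload)
        except json.JSONDecodeError as exc:
            raise LogParseError(f"line 1: bad header JSON: {exc}") from exc

        reader = csv.reader(fh)
        try:
            columns = next(reader)
        except StopIteration:
            raise LogParseError("line 2: missing column header") from None
        if columns != _COLUMNS:
            raise LogParseError(f"line 2: unexpected columns {columns}")

        # group rows by (session, trial), preserving order
        grouped: dict = {}
        order: list = []
        for lineno, raw in enumerate(reader, start=3):
            if not raw:
                continue
            if len(raw) != len(_COLUMNS):
                raise LogParseError(
                    f"line {lineno}: expected {len(_COLUMNS)} fields, got {len(raw)}"
                )
            try:
                row = {
                    "session": int(raw[0]),
                    "block": int(raw[1]),
                    "trial": int(raw[2]),
                    "trial_type": raw[3],
                    "event_kind": raw[4],
                    "x": float(raw[5]) if raw[5] else 0.0,
                    "y": float(raw[6]) if raw[6] else 0.0,
                    "t": float(raw[7]),
                    "ae_requirement": float(raw[8]),
                    "reinforced": bool(int(raw[9])),
                    "lineno": lineno,
                }
            except ValueError as exc:
                raise LogParseError(f"line {lineno}: {exc}") from exc
            key = (row["session"], row["trial"])
            if key not in grouped:
                grouped[key] = []
                order.append(key)
            grouped[key].append(row)

    meta_by_index = {m["session_index"]: m for m in header.get("sessions", [])}
    trials_by_session: dict = {idx: [] for idx in meta_by_index}
    lineno_of = {key[1]: grouped[key][0]["lineno"] for key in order}
    for session_idx, trial_idx in order:
        if session_idx not in meta_by_index:
            raise LogParseError(
                f"line {grouped[(session_idx, trial_idx)][0]['lineno']}: "
                f"session {session_idx} missing from the header"
            )
        trials_by_session[session_idx].append(
            _rebuild_trial(session_idx, grouped[(session_idx, trial_idx)], lineno_of)
        )

    sessions = []
    for idx in sorted(meta_by_index):
        m = meta_by_index[idx]
        expected = m.get("n_trials")
        found = len(trials_by_session.get(idx, []))
        if expected is not None and found != expected:
            raise LogParseError(
                f"session {idx}: header declares {expected} trials but the "
                f"file holds {found} (truncated or corrupted log)"
            )
        sessions.append(
            SessionLog(
                session_index=m["session_index"],
                condition_label=m["condition_label"],
                trials=trials_by_session.get(idx, []),
                mean_ae_requirement=m["mean_ae_requirement"],
                final_block_ae_requirement=m["final_block_ae_requirement"],
                carryover_requirement=m["carryover_requirement"],
                rng_seed=m["rng_seed"],
                ae_start=m["ae_start"],
            )
        )
    return sessions, header.get("metadata", {})
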