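"""Readers and writers for session and score tables.

Two on-disk representations are supported for raw sessions, both one
record per trial with the same five fields (session_id, position,
image_id, is_repeat, latency_ms):

* delimited text (CSV with a mandatory header row) — spreadsheet
  friendly;
* line-delimited JSON — one JSON object per line, nested-friendly.

An absent latency is an empty CSV field or JSON ``null``, never 0 or
3000 (3000 is a recorded timeout press and must stay distinguishable).
Score tables are CSV with a fixed, documented column order.  All
readers validate as they parse and raise :class:`ParseError` naming
the offending 1-based line number.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable

from .errors import ParseError, ValidationError
from .scoring import RawSession, SessionScore, TrialRecord

SCHEMA_VERSION = "1"
SESSION_FIELDS = ["session_id", "position", "image_id", "is_repeat", "latency_ms"]
SCORE_FIELDS = ["session_id", "hits", "misses", "correct_rejections",
                "false_alarms", "n_correct", "total_responses", "mean_hit_rt"]


def _trial_row(session_id: str, t: TrialRecord) -> dict:
    return {"session_id": session_id, "position": t.position,
            "image_id": t.image_id, "is_repeat": t.is_repeat,
            "latency_ms": t.latency_ms}


def _parse_trial(row: dict, line: int) -> tuple[str, TrialRecord]:
    try:
        session_id = str(row["session_id"])
        position = int(row["position"])
        image = str(row["image_id"])
        raw_repeat = row["is_repeat"]
        raw_latency = row["latency_ms"]
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed trial record: {exc}", line) from exc
    if isinstance(raw_repeat, bool):
        is_repeat = raw_repeat
    elif str(raw_repeat).lower() in {"true", "1"}:
        is_repeat = True
    elif str(raw_repeat).lower() in {"false", "0"}:
        is_repeat = False
    else:
        raise ParseError(f"is_repeat must be boolean, got {raw_repeat!r}", line)
    if raw_latency in (None, ""):
        latency = None
    else:
        try:
            latency = int(raw_latency)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"latency_ms must be an integer or absent, "
                             f"got {raw_latency!r}", line) from exc
    try:
        trial = TrialRecord(position=position, image_id=image,
                            is_repeat=is_repeat, latency_ms=latency)
    except ValidationError as exc:
        raise ParseError(str(exc), line) from exc
    return session_id, trial


def _assemble_sessions(keyed_trials: list[tuple[str, TrialRecord, int]]
                       ) -> list[RawSession]:
    by_session: dict[str, list[TrialRecord]] = {}
    seen: set[tuple[str, int]] = set()
    for session_id, trial, line in keyed_trials:
        key = (session_id, trial.position)
        if key in seen:
            raise ParseError(f"duplicate (session_id, position) {key}", line)
        seen.add(key)
        by_session.setdefault(session_id, []).append(trial)
    return [RawSession(session_id=sid,
                       trials=tuple(sorted(ts, key=lambda t: t.position)))
            for sid, ts in by_session.items()]


def write_sessions_csv(sessions: Iterable[RawSession], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=SESSION_FIELDS)
        writer.writeheader()
        for session in sessions:
            for trial in session.trials:
                row = _trial_row(session.session_id, trial)
                row["latency_ms"] = ("" if row["latency_ms"] is None
                                     else row["latency_ms"])
                writer.writerow(row)


def read_sessions_csv(path) -> list[RawSession]:
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise ParseError("empty file: missing header row", 1)
        if reader.fieldnames != SESSION_FIELDS:
            raise ParseError(f"expected header {SESSION_FIELDS}, "
                             f"got {reader.fieldnames}", 1)
        keyed = []
        for line, row in enumerate(reader, start=2):
            sid, trial = _parse_trial(row, line)
            keyed.append((sid, trial, line))
    return _assemble_sessions(keyed)


def write_sessions_jsonl(sessions: Iterable[RawSession], path) -> None:
    with open(path, "w") as handle:
        for session in sessions:
            for trial in session.trials:
                handle.write(json.dumps(_trial_row(session.session_id, trial)))
                handle.write("\n")


def read_sessions_jsonl(path) -> list[RawSession]:
    keyed: list[tuple[str, TrialRecord, int]] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                row = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"invalid JSON: {exc}", line_no) from exc
            sid, trial = _parse_trial(row, line_no)
            keyed.append((sid, trial, line_no))
    return _assemble_sessions(keyed)


def write_scores_csv(scores: Iterable[SessionScore], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=SCORE_FIELDS)
        writer.writeheader()
        for s in scores:
            writer.writerow({
                "session_id": "" if s.session_id is None else s.session_id,
                "hits": s.hits, "misses": s.misses,
                "correct_rejections": s.correct_rejections,
                "false_alarms": s.false_alarms, "n_correct": s.n_correct,
                "total_responses": s.total_responses,
                "mean_hit_rt": ("" if s.mean_hit_rt is None
                                else f"{s.mean_hit_rt:.3f}"),
            })


def read_scores_csv(path) -> list[SessionScore]:
    scores: list[SessionScore] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise ParseError("empty file: missing header row", 1)
        if reader.fieldnames != SCORE_FIELDS:
            raise ParseError(f"expected header {SCORE_FIELDS}, "
                             f"got {reader.fieldnames}", 1)
        for line, row in enumerate(reader, start=2):
            try:
                scores.append(SessionScore(
                    session_id=row["session_id"] or None,
                    hits=int(row["hits"]), misses=int(row["misses"]),
                    correct_rejections=int(row["correct_rejections"]),
                    false_alarms=int(row["false_alarms"]),
                    n_correct=int(row["n_correct"]),
                    total_responses=int(row["total_responses"]),
                    mean_hit_rt=(float(row["mean_hit_rt"])
                                 if row["mean_hit_rt"] else None),
                ))
            except (KeyError, TypeError, ValueError, ValidationError) as exc:
                raise ParseError(f"malformed score record: {exc}", line) from exc
    return scores


def read_sessions(path) -> list[RawSession]:
    """Dispatch on suffix: .jsonl/.ndjson as line-delimited JSON, else CSV."""
    if Path(path).suffix.lower() in {".jsonl", ".ndjson"}:
        return read_sessions_jsonl(path)
    return read_sessions_csv(path)


def write_sessions(sessions: Iterable[RawSession], path) -> None:
    if Path(path).suffix.lower() in {".jsonl", ".ndjson"}:
        write_sessions_jsonl(sessions, path)
    else:
        write_sessions_csv(sessions, path)
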