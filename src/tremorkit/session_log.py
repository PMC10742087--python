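"""Time-stamped session logs and adherence (completion) metrics.

The log is an append-only JSON-lines file, one self-describing record per
line with a required ``schema_version``.  Completion fractions are
duration-weighted: completed seconds over scheduled seconds, with missing
protocol days counted as zero completed out of their full scheduled
duration.  "At home" covers days 2 onward; day 1 is the supervised
in-clinic session.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from datetime import datetime

from .errors import SessionLogError

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class SessionLogEntry:
    """One session's record: when it started and how much was completed."""

    day: int
    started_at: str  # ISO-8601 with timezone offset
    completed_duration: float  # s
    scheduled_duration: float  # s
    baseline_frequency: float  # Hz
    baseline_significant: bool
    ended_early: bool

    def __post_init__(self) -> None:
        if self.day < 1:
            raise SessionLogError(f"day must be >= 1, got {self.day}")
        if not 0 <= self.completed_duration <= self.scheduled_duration:
            raise SessionLogError(
                f"completed_duration {self.completed_duration} outside "
                f"[0, {self.scheduled_duration}]"
            )
        if self.ended_early != (self.completed_duration < self.scheduled_duration):
            raise SessionLogError("ended_early inconsistent with durations")
        try:
            datetime.fromisoformat(self.started_at)
        except ValueError as exc:
            raise SessionLogError(f"started_at not ISO-8601: {self.started_at!r}") from exc


def append_entry(path, entry: SessionLogEntry) -> None:
    """Append one entry to the JSON-lines log (created if absent)."""
    record = {"schema_version": SCHEMA_VERSION, **asdict(entry)}
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(record) + "\n")


def read_log(path) -> list[SessionLogEntry]:
    """Read every entry back; malformed lines are reported by number."""
    entries: list[SessionLogEntry] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SessionLogError(f"{path}: malformed record on line {lineno}") from exc
            if not isinstance(record, dict):
                raise SessionLogError(f"{path}: malformed record on line {lineno}")
            version = record.pop("schema_version", None)
            if version != SCHEMA_VERSION:
                raise SessionLogError(
                    f"{path}: line {lineno}: schema version {version!r} "
                    f"(expected {SCHEMA_VERSION})"
                )
            try:
                entries.append(SessionLogEntry(**record))
            except (TypeError, SessionLogError) as exc:
                raise SessionLogError(
                    f"{path}: invalid record on line {lineno}: {exc}"
                ) from exc
    return entries


@dataclass(frozen=True)
class CompletionMetrics:
    """Duration-weighted adherence per day and aggregated."""

    per_day: dict[int, float]  # day -> completed/scheduled, in [0, 1]
    at_home_fraction: float  # days 2..n_days pooled
    overall_fraction: float  # all protocol days pooled


def completion_metrics(entries: list[SessionLogEntry], cfg) -> CompletionMetrics:
    """Aggregate completion fractions over the protocol.

    Duplicate entries for a day are rejected — the protocol defines one
    session per day.  Days without an entry contribute zero completed time
    against their full scheduled duration from `cfg`.
    """
    from .protocol import scheduled_duration  # deferred: protocol imports this module

    by_day: dict[int, SessionLogEntry] = {}
    for entry in entries:
        if entry.day > cfg.n_days:
            raise SessionLogError(
                f"entry for day {entry.day} outside the {cfg.n_days}-day protocol"
            )
        if entry.day in by_day:
            raise SessionLogError(f"duplicate entry for day {entry.day}")
        by_day[entry.day] = entry

    per_day: dict[int, float] = {}
    completed = {}
    scheduled = {}
    for day in range(1, cfg.n_days + 1):
        if day in by_day:
            completed[day] = by_day[day].completed_duration
            scheduled[day] = by_day[day].scheduled_duration
        else:
            completed[day] = 0.0
            scheduled[day] = scheduled_duration(day, cfg)
        per_day[day] = completed[day] / scheduled[day]

    def pooled(days) -> float:
        sched = sum(scheduled[d] for d in days)
        return sum(completed[d] for d in days) / sched if sched > 0 else 0.0

    return CompletionMetrics(
        per_day=per_day,
        at_home_fraction=pooled(range(2, cfg.n_days + 1)),
        overall_fraction=pooled(range(1, cfg.n_days + 1)),
    )
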