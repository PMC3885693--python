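"""Reading and writing participant tables.

The on-disk format is a delimited text table with a header, one row per
respondent.  Canonical column names are listed in :data:`CANONICAL_COLUMNS`;
a ``column_map`` lets a file with different headers (for example a deposited
study table) be read without editing it.  Blank cells are read as missing,
never silently as zero — zero-filling is an explicit analysis step.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .forest import RecruitmentForest
from .records import (
    CHANNELS,
    LOCATIONS,
    MEALS,
    ParticipantRecord,
    TRAVEL_MODES,
    validate_unique_pids,
)

_COUNT_COLUMNS = (
    ["age", "household_size", "household_symptomatic"]
    + [f"travel_{m}" for m in TRAVEL_MODES]
    + [f"loc_{l}" for l in LOCATIONS]
    + [f"eat_{m}" for m in MEALS]
)

#: Column names written by :func:`write_participants`.
CANONICAL_COLUMNS = (
    ["pid", "recruiter_pid", "channel", "completed", "age", "gender",
     "education", "region_code", "household_size"]
    + [f"travel_{m}" for m in TRAVEL_MODES]
    + [f"loc_{l}" for l in LOCATIONS]
    + [f"eat_{m}" for m in MEALS]
    + ["symptoms", "household_symptomatic", "diary_weekday"]
)


@dataclass
class DialectConfig:
    """Delimited-text dialect and header mapping.

    ``column_map`` maps canonical names to the file's actual headers, e.g.
    ``{"pid": "ID", "recruiter_pid": "RecruiterID"}``.  Unmapped canonical
    names are looked up under their own name; unrecognized file columns are
    preserved verbatim in ``ParticipantRecord.extra``.
    """

    delimiter: str = ","
    encoding: str = "utf-8"
    column_map: dict = field(default_factory=dict)
    missing_tokens: tuple = ("", "NA", "NaN", "nan", "null")

    def source_column(self, canonical: str) -> str:
        return self.column_map.get(canonical, canonical)


class MalformedRowError(ValueError):
    """Raised when rows contain unparseable counts; carries row numbers."""

    def __init__(self, problems):
        self.problems = problems
        detail = "; ".join(f"row {row}: {msg}" for row, msg in problems)
        super().__init__(f"malformed participant rows: {detail}")


def _parse_int(token: str, config: DialectConfig) -> Optional[int]:
    if token is None or token.strip() in config.missing_tokens:
        return None
    value = int(float(token))
    if value < 0:
        raise ValueError(f"negative count {token!r}")
    return value


def read_participants(
    path, config: Optional[DialectConfig] = None
) -> list[ParticipantRecord]:
    """Read a participant table into records.

    Raises :class:`MalformedRowError` listing offending row numbers when
    counts cannot be parsed, and ``ValueError`` on duplicated pids.
    """
    config = config or DialectConfig()
    problems = []
    records = []
    with open(path, newline="", encoding=config.encoding) as fh:
        reader = csv.DictReader(fh, delimiter=config.delimiter)
        if reader.fieldnames is None or config.source_column("pid") not in reader.fieldnames:
            raise ValueError(f"{path}: header must name a {config.source_column('pid')!r} column")
        known = {config.source_column(c) for c in CANONICAL_COLUMNS}
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_row_to_record(row, config, known))
            except ValueError as exc:
                problems.append((lineno, str(exc)))
    if problems:
        raise MalformedRowError(problems)
    validate_unique_pids(records)
    return records


def _row_to_record(row: dict, config: DialectConfig, known: set) -> ParticipantRecord:
    def get(canonical: str) -> Optional[str]:
        tok = row.get(config.source_column(canonical))
        if tok is None or tok.strip() in config.missing_tokens:
            return None
        return tok.strip()

    def get_int(canonical: str) -> Optional[int]:
        return _parse_int(row.get(config.source_column(canonical)), config)

    pid = get("pid")
    if pid is None:
        raise ValueError("missing pid")
    channel = get("channel") or "unknown"
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    completed_tok = get("completed")
    completed = (
        True
        if completed_tok is None
        else completed_tok.lower() in ("1", "true", "yes", "y")
    )
    symptoms_tok = get("symptoms")
    symptoms = set(s for s in (symptoms_tok or "").split(";") if s)
    extra = {
        k: v for k, v in row.items() if k not in known and v not in (None, "")
    }
    return ParticipantRecord(
        pid=pid,
        recruiter_pid=get("recruiter_pid"),
        channel=channel,
        completed=completed,
        age=get_int("age"),
        gender=get("gender"),
        education=get("education"),
        region_code=get("region_code"),
        household_size=get_int("household_size"),
        travel_contacts={
            m: v for m in TRAVEL_MODES if (v := get_int(f"travel_{m}")) is not None
        },
        location_contacts={
            l: v for l in LOCATIONS if (v := get_int(f"loc_{l}")) is not None
        },
        eating_contacts={
            m: v for m in MEALS if (v := get_int(f"eat_{m}")) is not None
        },
        symptoms=symptoms,
        household_symptomatic=get_int("household_symptomatic"),
        diary_weekday=get("diary_weekday"),
        extra=extra,
    )


def write_participants(records: Iterable[ParticipantRecord], path) -> None:
    """Write records in the canonical table format (round-trips with read)."""
    records = list(records)
    extra_cols = sorted({k for r in records for k in r.extra})
    cols = CANONICAL_COLUMNS + extra_cols
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for r in records:
            row = {
                "pid": r.pid,
                "recruiter_pid": r.recruiter_pid,
                "channel": r.channel,
                "completed": "true" if r.completed else "false",
                "age": r.age,
                "gender": r.gender,
                "education": r.education,
                "region_code": r.region_code,
                "household_size": r.household_size,
                "symptoms": ";".join(sorted(r.symptoms)),
                "household_symptomatic": r.household_symptomatic,
                "diary_weekday": r.diary_weekday,
            }
            for m in TRAVEL_MODES:
                row[f"travel_{m}"] = r.travel_contacts.get(m)
            for l in LOCATIONS:
                row[f"loc_{l}"] = r.location_contacts.get(l)
            for m in MEALS:
                row[f"eat_{m}"] = r.eating_contacts.get(m)
            row.update(r.extra)
            writer.writerow(["" if row.get(c) is None else row.get(c) for c in cols])


def recruitment_summary(
    records: Iterable[ParticipantRecord],
    forest: RecruitmentForest,
    coupons: int = 4,
) -> dict:
    """Tally recruitment success by invitation channel.

    A respondent counts as a recruiter once at least one of their invitees
    appears in the table; their channel is the most common channel among
    their invitees.  A recruitment is successful when the invitee completed
    the survey.  Returns a dict with a per-channel table (counts of
    recruiters by 0..coupons successes), total successful recruitments per
    channel, and overall coupon / entry / completion totals.
    """
    records = list(records)
    by_pid = {r.pid: r for r in records}
    per_recruiter: dict[str, dict] = {}
    for rec in records:
        if rec.recruiter_pid is None or rec.recruiter_pid not in by_pid:
            continue
        slot = per_recruiter.setdefault(
            rec.recruiter_pid, {"channels": [], "successes": 0}
        )
        slot["channels"].append(rec.channel)
        if rec.completed:
            slot["successes"] += 1

    channels = sorted({c for slot in per_recruiter.values() for c in slot["channels"]})
    table = pd.DataFrame(
        0, index=channels, columns=list(range(coupons + 1)), dtype=int
    )
    successes_by_channel = {c: 0 for c in channels}
    for slot in per_recruiter.values():
        channel = max(set(slot["channels"]), key=slot["channels"].count)
        k = min(slot["successes"], coupons)
        table.loc[channel, k] += 1
        successes_by_channel[channel] += slot["successes"]

    n_recruiters = len(per_recruiter)
    coupons_issued = coupons * n_recruiters
    entries = sum(1 for r in records if r.recruiter_pid is not None)
    completions = sum(
        1 for r in records if r.recruiter_pid is not None and r.completed
    )
    total_successes = sum(successes_by_channel.values())
    return {
        "by_channel": table,
        "successes_by_channel": successes_by_channel,
        "total_successful_recruitments": total_successes,
        "n_recruiters": n_recruiters,
        "coupons_issued": coupons_issued,
        "entries": entries,
        "completions": completions,
        "entry_rate": entries / coupons_issued if coupons_issued else float("nan"),
        "completion_rate": completions / coupons_issued if coupons_issued else float("nan"),
        "success_share_by_channel": {
            c: (successes_by_channel[c] / total_successes if total_successes else float("nan"))
            for c in channels
        },
    }
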