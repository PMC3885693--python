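"""Analysis variables derived from the raw contact diary.

The diary records contact counts per travel mode, location and shared meal.
``degree`` — the number of distinct close contacts in the diary day — is the
sum of travel and location contacts, censored at a cap (default 500) beyond
which self-reports were judged unreliable; contacts while eating are censored
at 75.  Household members are enumerated by a separate roster question and do
not enter degree.  Blank diary cells mean "not applicable" for respondents
who finished the questionnaire, so they are zero-filled for completers only;
incomplete records keep their missing values and drop out of count-based
analyses.

Count variables are heavily right-skewed, so correlation analyses use a log
transform.  Zero counts are legitimate (a respondent may meet nobody), hence
the default convention ``log1p``: ``log(x + 1)``, which maps 0 to 0 and keeps
every respondent.  ``log`` (natural log with zeros excluded) is available for
sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .records import (
    FLU_SYMPTOM_SET,
    COLD_SYMPTOM_SET,
    LOCATIONS,
    MEALS,
    ParticipantRecord,
    TRAVEL_MODES,
)

DEGREE_CAP = 500
EATING_CAP = 75


@dataclass
class DerivedMeasures:
    """Per-respondent analysis variables (see module docstring)."""

    pid: str
    degree: int
    travel_total: int
    location_total: int
    eating_total: int
    log_degree: float
    log_household: Optional[float]
    log_eating: float
    symptom_count: int
    two_plus_symptoms: bool
    flu_like: bool
    cold_like: bool


def zero_fill(record: ParticipantRecord) -> ParticipantRecord:
    """Replace missing counts by zero for completed records.

    Non-completed records are returned unchanged: their blanks are genuine
    missingness, not implicit zeros.
    """
    if not record.completed:
        return record
    return record.copy(
        travel_contacts={m: record.travel_contacts.get(m) or 0 for m in TRAVEL_MODES},
        location_contacts={l: record.location_contacts.get(l) or 0 for l in LOCATIONS},
        eating_contacts={m: record.eating_contacts.get(m) or 0 for m in MEALS},
        household_size=record.household_size if record.household_size is not None else 0,
        household_symptomatic=(
            record.household_symptomatic
            if record.household_symptomatic is not None
            else 0
        ),
    )


def _log_transform(x: Optional[float], convention: str) -> Optional[float]:
    if x is None:
        return None
    if convention == "log1p":
        return math.log1p(x)
    if convention == "log":
        return math.log(x) if x > 0 else None
    raise ValueError(f"unknown log convention {convention!r}")


def derive_measures(
    record: ParticipantRecord,
    degree_cap: int = DEGREE_CAP,
    eating_cap: int = EATING_CAP,
    log_convention: str = "log1p",
    flu_set: frozenset = FLU_SYMPTOM_SET,
    cold_set: frozenset = COLD_SYMPTOM_SET,
) -> DerivedMeasures:
    """Compute degree, eating totals, censoring and log transforms.

    The record must be zero-filled and completed; negative counts raise.
    """
    if not record.completed:
        raise ValueError(f"record {record.pid} is not completed; derive after filtering")
    counts = (
        list(record.travel_contacts.values())
        + list(record.location_contacts.values())
        + list(record.eating_contacts.values())
    )
    if any(c is None for c in counts):
        raise ValueError(f"record {record.pid} has missing counts; zero_fill first")
    if any(c < 0 for c in counts):
        raise ValueError(f"record {record.pid} has negative counts")

    travel_total = sum(record.travel_contacts.values())
    location_total = sum(record.location_contacts.values())
    degree = min(degree_cap, travel_total + location_total)
    eating_total = min(eating_cap, sum(record.eating_contacts.values()))
    symptom_count = len(record.symptoms)
    return DerivedMeasures(
        pid=record.pid,
        degree=degree,
        travel_total=travel_total,
        location_total=location_total,
        eating_total=eating_total,
        log_degree=_log_transform(degree, log_convention),
        log_household=_log_transform(record.household_size, log_convention),
        log_eating=_log_transform(eating_total, log_convention),
        symptom_count=symptom_count,
        two_plus_symptoms=symptom_count >= 2,
        flu_like=flu_set <= record.symptoms,
        cold_like=cold_set <= record.symptoms,
    )


def measures_frame(
    records: Iterable[ParticipantRecord],
    degree_cap: int = DEGREE_CAP,
    eating_cap: int = EATING_CAP,
    log_convention: str = "log1p",
) -> pd.DataFrame:
    """Zero-fill completed records and assemble derived measures plus
    demographics into one DataFrame indexed by pid.  Incomplete records are
    dropped (they cannot contribute to count-based analyses)."""
    rows = []
    for rec in records:
        if not rec.completed:
            continue
        filled = zero_fill(rec)
        m = derive_measures(filled, degree_cap, eating_cap, log_convention)
        rows.append(
            {
                "pid": rec.pid,
                "recruiter_pid": rec.recruiter_pid,
                "age": rec.age,
                "gender": rec.gender,
                "education": rec.education,
                "household_size": filled.household_size,
                "diary_weekday": rec.diary_weekday,
                "degree": m.degree,
                "travel_total": m.travel_total,
                "location_total": m.location_total,
                "eating_total": m.eating_total,
                "log_degree": m.log_degree,
                "log_household": m.log_household,
                "log_eating": m.log_eating,
                "symptom_count": m.symptom_count,
                "two_plus_symptoms": m.two_plus_symptoms,
                "flu_like": m.flu_like,
                "cold_like": m.cold_like,
            }
        )
    return pd.DataFrame(rows).set_index("pid", drop=False) if rows else pd.DataFrame()


_AGE_BINS = [(14, 19), (20, 29), (30, 39), (40, 200)]


def _age_class(age) -> Optional[str]:
    if age is None or (isinstance(age, float) and math.isnan(age)):
        return None
    for lo, hi in _AGE_BINS:
        if lo <= age <= hi:
            return f"{lo}-{hi}" if hi < 200 else f"{lo}+"
    return "<14"


GROUP_KEYS = ("age_class", "gender", "education", "household_size", "diary_weekday")


def setting_summaries(
    records: Iterable[ParticipantRecord],
    group_by: str,
    **derive_kwargs,
) -> pd.DataFrame:
    """Mean / median / SD of travel, location and total contacts per stratum.

    ``group_by`` is one of :data:`GROUP_KEYS`.  Strata with no records are
    omitted; respondents missing the grouping variable are tallied under
    ``"missing"`` with their count only, mirroring how descriptive tables
    report missingness.
    """
    if group_by not in GROUP_KEYS:
        raise ValueError(f"unknown group_by {group_by!r}; choose from {GROUP_KEYS}")
    df = measures_frame(records, **derive_kwargs)
    if df.empty:
        raise ValueError("no completed records to summarise")
    if group_by == "age_class":
        df = df.assign(age_class=df["age"].map(_age_class))
    key = df[group_by]
    out_rows = []
    for stratum, sub in df[key.notna()].groupby(key, observed=True):
        row = {"stratum": stratum, "n": len(sub)}
        for var in ("travel_total", "location_total", "degree"):
            row[f"{var}_mean"] = float(sub[var].mean())
            row[f"{var}_median"] = float(sub[var].median())
            row[f"{var}_sd"] = float(sub[var].std(ddof=1)) if len(sub) > 1 else 0.0
        out_rows.append(row)
    n_missing = int(key.isna().sum())
    if n_missing:
        out_rows.append({"stratum": "missing", "n": n_missing})
    return pd.DataFrame(out_rows)
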