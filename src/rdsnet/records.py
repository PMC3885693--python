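"""Participant records for a respondent-driven contact-diary survey.

One record per respondent: who recruited them, which invitation channel was
used, demographics, household composition, per-setting contact counts from a
one-day diary, and self-reported influenza-like-illness symptoms.  Counts may
be missing (``None``); missingness is preserved at read time and resolved by
an explicit zero-fill step (see :mod:`rdsnet.diary`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

#: Travel modes with a contact-count question in the diary.
TRAVEL_MODES = ("mass_transport", "bus", "car_taxi", "motorbike")

#: Named locations with a contact-count question in the diary.
LOCATIONS = (
    "home",
    "work",
    "school_university",
    "restaurant_coffee",
    "sport_leisure",
    "concert",
    "other",
)

#: Shared-meal occasions with a contact-count question.
MEALS = ("breakfast", "lunch", "dinner", "snack")

#: Recruitment channels offered by the survey system.
CHANNELS = ("facebook", "direct_email", "forwarded_email", "unknown")

#: Ordinal education levels, lowest first.
EDUCATION_LEVELS = ("below_bachelor", "bachelor", "master_or_higher")

GENDERS = ("female", "male")

#: Symptom vocabulary used in the self-report checklist.
SYMPTOMS = (
    "fever",
    "headache",
    "muscle_pain",
    "runny_nose",
    "sore_throat",
    "cough",
    "sneezing",
    "fatigue",
)

#: Symptom combination read as influenza-like.
FLU_SYMPTOM_SET = frozenset({"fever", "headache", "muscle_pain"})

#: Symptom combination read as common-cold-like.
COLD_SYMPTOM_SET = frozenset({"runny_nose", "sore_throat", "cough"})

WEEKDAYS = ("mon", "tue", "wed", "thu", "fri", "sat", "sun")


@dataclass
class ParticipantRecord:
    """One respondent row.

    ``recruiter_pid is None`` marks a seed.  Count fields hold ``None`` when
    the respondent left the answer blank; keys absent from the contact maps
    are likewise treated as missing.
    """

    pid: str
    recruiter_pid: Optional[str] = None
    channel: str = "unknown"
    completed: bool = True
    age: Optional[int] = None
    gender: Optional[str] = None
    education: Optional[str] = None
    region_code: Optional[str] = None
    household_size: Optional[int] = None
    travel_contacts: dict = field(default_factory=dict)
    location_contacts: dict = field(default_factory=dict)
    eating_contacts: dict = field(default_factory=dict)
    symptoms: set = field(default_factory=set)
    household_symptomatic: Optional[int] = None
    diary_weekday: Optional[str] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pid:
            raise ValueError("pid must be a non-empty string")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        for name, counts in (
            ("travel_contacts", self.travel_contacts),
            ("location_contacts", self.location_contacts),
            ("eating_contacts", self.eating_contacts),
        ):
            for key, value in counts.items():
                if value is not None and value < 0:
                    raise ValueError(f"{name}[{key}] is negative for pid {self.pid}")

    @property
    def is_seed(self) -> bool:
        return self.recruiter_pid is None

    def copy(self, **changes) -> "ParticipantRecord":
        return replace(self, **changes)


def validate_unique_pids(records) -> None:
    """Raise ``ValueError`` listing every duplicated pid, if any."""
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.pid] = seen.get(rec.pid, 0) + 1
    dupes = sorted(pid for pid, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"duplicate pid(s): {', '.join(dupes)}")
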