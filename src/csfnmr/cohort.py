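"""Longitudinal study-design logic: visit selection, progression arithmetic
and nested case cohorts.

Patients are sampled every six months; to avoid pseudo-replication only the
most advanced sample (largest months-from-enrolment) of each patient enters
any model.  Nested cohorts are defined by a minimum follow-up at that sample
("at least X months from enrolment", inclusive) or, alternatively, a minimum
disease duration at sampling (strictly greater than the threshold).  The
clinical progression rate is (48 - ALSFRS-R) / disease duration in points
per month; 1 point/month splits slow from fast progressors (the boundary is
slow).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Visit",
    "Patient",
    "CohortSpec",
    "CohortSelection",
    "EmptyPatientError",
    "CohortError",
    "progression_rate",
    "most_advanced_sample",
    "build_cohort",
    "split_by_progression",
    "load_roster",
    "save_roster",
]

ALSFRS_MAX = 48

GROUPS = ("ALS", "PLS", "control")


class EmptyPatientError(ValueError):
    pass


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class Visit:
    """One sampling visit.  Controls carry no duration or ALSFRS-R."""

    patient_id: str
    sample_id: str
    months_from_enrolment: float
    disease_duration_months: float | None = None
    alsfrs_r: int | None = None

    def __post_init__(self) -> None:
        if self.months_from_enrolment < 0:
            raise ValueError("months_from_enrolment must be >= 0")
        if self.disease_duration_months is not None and not self.disease_duration_months > 0:
            raise ValueError("disease_duration_months must be > 0")
        if self.alsfrs_r is not None and not 0 <= self.alsfrs_r <= ALSFRS_MAX:
            raise ValueError(f"alsfrs_r must lie in [0, {ALSFRS_MAX}]")


@dataclass
class Patient:
    patient_id: str
    group: str
    visits: list[Visit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        self.visits = sorted(self.visits, key=lambda v: v.months_from_enrolment)
        if self.group == "control" and len(self.visits) != 1:
            raise ValueError(
                f"control {self.patient_id!r} must have exactly one visit "
                "(single time-point sampling)"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Inclusion rule for the case arm of one model.

    Exactly one of ``min_months_from_enrolment`` (inclusive) or
    ``min_duration_months`` (strict) must be set.
    """

    min_months_from_enrolment: float | None = None
    min_duration_months: float | None = None
    include_pls: bool = False

    def __post_init__(self) -> None:
        if (self.min_months_from_enrolment is None) == (self.min_duration_months is None):
            raise ValueError("set exactly one of the enrolment/duration thresholds")

    def admits(self, visit: Visit) -> bool:
        if self.min_months_from_enrolment is not None:
            return visit.months_from_enrolment >= self.min_months_from_enrolment
        if visit.disease_duration_months is None:
            return False
        return visit.disease_duration_months > self.min_duration_months


@dataclass
class CohortSelection:
    case_sample_ids: list[str]
    control_sample_ids: list[str]

    @property
    def n_cases(self) -> int:
        return len(self.case_sample_ids)

    @property
    def n_controls(self) -> int:
        return len(self.control_sample_ids)


def progression_rate(alsfrs_r: int, duration_months: float) -> float:
    """(48 - ALSFRS-R) / disease duration, in points lost per month."""
    if not 0 <= alsfrs_r <= ALSFRS_MAX:
        raise ValueError(f"alsfrs_r must lie in [0, {ALSFRS_MAX}]")
    if duration_months <= 0:
        raise ValueError("disease duration must be positive")
    return (ALSFRS_MAX - alsfrs_r) / duration_months


def most_advanced_sample(patient: Patient) -> Visit:
    """The visit furthest along the disease course.

    Maximal months-from-enrolment; ties broken by the later disease duration,
    then by the lexically first sample id.
    """
    if not patient.visits:
        raise EmptyPatientError(f"patient {patient.patient_id!r} has no visits")

    def key(v: Visit):
        dur = v.disease_duration_months if v.disease_duration_months is not None else -1.0
        return (-v.months_from_enrolment, -dur, v.sample_id)

    return sorted(patient.visits, key=key)[0]


def build_cohort(patients: Sequence[Patient], spec: CohortSpec) -> CohortSelection:
    """Select one case sample per patient under the spec; keep all controls.

    PLS patients (slowly progressive variant) are appended whenever
    ``include_pls`` is set — the design adds all five to each model.
    """
    cases: list[str] = []
    controls: list[str] = []
    for p in patients:
        if p.group == "control":
            controls.append(p.visits[0].sample_id)
        elif p.group == "ALS":
            v = most_advanced_sample(p)
            if spec.admits(v):
                cases.append(v.sample_id)
        elif p.group == "PLS" and spec.include_pls:
            cases.append(most_advanced_sample(p).sample_id)
    if not cases:
        raise CohortError("no case patient satisfies the cohort spec")
    if not controls:
        raise CohortError("no control samples in the roster")
    return CohortSelection(cases, controls)


def split_by_progression(
    patients: Sequence[Patient], cutoff: float = 1.0
) -> tuple[list[str], list[str]]:
    """Split ALS patients into slow (rate <= cutoff) and fast (rate > cutoff).

    The rate is evaluated at each patient's most advanced sample; returns
    (slow sample ids, fast sample ids).
    """
    slow: list[str] = []
    fast: list[str] = []
    for p in patients:
        if p.group != "ALS":
            continue
        v = most_advanced_sample(p)
        if v.alsfrs_r is None or v.disease_duration_months is None:
            raise ValueError(f"visit {v.sample_id!r} lacks ALSFRS-R or duration")
        rate = progression_rate(v.alsfrs_r, v.disease_duration_months)
        (slow if rate <= cutoff else fast).append(v.sample_id)
    return slow, fast


# ---------------------------------------------------------------------------
# Roster I/O

_ROSTER_COLUMNS = [
    "patient_id",
    "group",
    "sample_id",
    "months_from_enrolment",
    "disease_duration_months",
    "alsfrs_r",
]


def save_roster(patients: Iterable[Patient], path: str | Path) -> None:
    rows = []
    for p in patients:
        for v in p.visits:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "group": p.group,
                    "sample_id": v.sample_id,
                    "months_from_enrolment": v.months_from_enrolment,
                    "disease_duration_months": v.disease_duration_months,
                    "alsfrs_r": v.alsfrs_r,
                }
            )
    pd.DataFrame(rows, columns=_ROSTER_COLUMNS).to_csv(path, index=False)


def load_roster(path: str | Path) -> list[Patient]:
    df = pd.read_csv(path)
    missing = set(_ROSTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"roster is missing columns: {sorted(missing)}")
    patients: dict[str, Patient] = {}
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        dur = row["disease_duration_months"]
        score = row["alsfrs_r"]
        visit = Visit(
            patient_id=pid,
            sample_id=str(row["sample_id"]),
            months_from_enrolment=float(row["months_from_enrolment"]),
            disease_duration_months=None if pd.isna(dur) else float(dur),
            alsfrs_r=None if pd.isna(score) else int(score),
        )
        if pid not in patients:
            patients[pid] = Patient(pid, str(row["group"]), [visit])
        else:
            patients[pid].visits = sorted(
                patients[pid].visits + [visit], key=lambda v: v.months_from_enrolment
            )
    return list(patients.values())
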