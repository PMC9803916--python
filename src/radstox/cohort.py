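"""Trial-cohort containers, validation, and delimited-text I/O.

The unit of analysis is a randomized postmastectomy-radiotherapy trial in
which patients are stratified by skin involvement (standard vs high risk),
randomized to a chest-wall bolus regimen within their stratum, and followed
with weekly radiodermatitis grading (RTOG/EORTC acute scale, 0-4) during
~5.6 weeks of treatment plus two post-treatment visits. Two flat files hold
everything: a per-patient table (stratum, arm, covariates, oncologic
outcomes) and a per-visit toxicity table (week, grade, visit kind).

Grades are opaque ordinal labels here; no clinical semantics are attached.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Optional, Tuple

from .exceptions import CohortValidationError, SchemaError

RISK_STRATA = ("standard", "high")
ARMS = ("no_bolus", "alternate", "daily")
BMI_STRATA = ("lt30", "ge30")
RT_TECHNIQUES = ("conventional", "ct_planned")
VISIT_KINDS = ("on_treatment", "post_treatment")

#: Arms admissible within each risk stratum: patients with skin involvement
#: are never randomized to no bolus, and standard-risk patients never to
#: daily bolus.
ARM_MENU = {
    "standard": ("no_bolus", "alternate"),
    "high": ("alternate", "daily"),
}

MAX_GRADE = 4

PATIENT_COLUMNS = [
    "patient_id",
    "risk_stratum",
    "arm",
    "bmi_stratum",
    "age_years",
    "diabetes",
    "smoking_ever",
    "rt_technique",
    "local_failure",
    "local_failure_time_years",
    "followup_years",
    "metastasis_at_or_before_rt",
]

TOXICITY_COLUMNS = ["patient_id", "week", "grade", "visit_kind", "bolus_stopped"]


@dataclass(frozen=True)
class GradeObservation:
    """A single weekly toxicity evaluation."""

    week: float
    grade: int
    visit_kind: str = "on_treatment"

    def __post_init__(self):
        if self.visit_kind not in VISIT_KINDS:
            raise ValueError(f"visit_kind must be one of {VISIT_KINDS}, got {self.visit_kind!r}")
        if not (isinstance(self.grade, int) and 0 <= self.grade <= MAX_GRADE):
            raise ValueError(f"grade must be an integer in 0..{MAX_GRADE}, got {self.grade!r}")
        if not (self.week > 0 and math.isfinite(self.week)):
            raise ValueError(f"week must be a positive finite number, got {self.week!r}")


@dataclass(frozen=True)
class ToxicityTrajectory:
    """Ordered weekly grade observations for one patient.

    ``bolus_stopped_week`` marks the visit at which bolus use was
    discontinued; per protocol this happens upon a grade-3 event, so an
    observation with grade >= 3 must exist at or before that week.
    """

    patient_id: str
    observations: Tuple[GradeObservation, ...]
    bolus_stopped_week: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "observations", tuple(self.observations))
        weeks = [o.week for o in self.observations]
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise CohortValidationError(
                "observations must be sorted by week with no duplicates",
                [self.patient_id],
            )
        on = [o.week for o in self.observations if o.visit_kind == "on_treatment"]
        post = [o.week for o in self.observations if o.visit_kind == "post_treatment"]
        if on and post and min(post) <= max(on):
            raise CohortValidationError(
                "post-treatment weeks must strictly exceed all on-treatment weeks",
                [self.patient_id],
            )
        if self.bolus_stopped_week is not None:
            if not any(
                o.grade >= 3 and o.week <= self.bolus_stopped_week
                for o in self.observations
            ):
                raise CohortValidationError(
                    "bolus_stopped_week set but no grade >= 3 observation at or "
                    "before that week",
                    [self.patient_id],
                )

    @property
    def weeks(self) -> Tuple[float, ...]:
        return tuple(o.week for o in self.observations)

    @property
    def grades(self) -> Tuple[int, ...]:
        return tuple(o.grade for o in self.observations)

    @property
    def max_grade(self) -> int:
        return max(self.grades) if self.observations else 0

    @property
    def last_week(self) -> float:
        return self.observations[-1].week


@dataclass(frozen=True)
class Patient:
    patient_id: str
    risk_stratum: str
    arm: str
    bmi_stratum: str
    age_years: float
    diabetes: bool
    smoking_ever: bool
    rt_technique: str
    local_failure: bool = False
    local_failure_time_years: Optional[float] = None
    followup_years: float = 0.0
    metastasis_at_or_before_rt: bool = False

    def __post_init__(self):
        if self.risk_stratum not in RISK_STRATA:
            raise CohortValidationError(
                f"risk_stratum must be one of {RISK_STRATA}, got {self.risk_stratum!r}",
                [self.patient_id],
            )
        if self.arm not in ARMS:
            raise CohortValidationError(
                f"arm must be one of {ARMS}, got {self.arm!r}", [self.patient_id]
            )
        if self.arm not in ARM_MENU[self.risk_stratum]:
            raise CohortValidationError(
                f"arm {self.arm!r} is not admissible in stratum {self.risk_stratum!r}",
                [self.patient_id],
            )
        if self.bmi_stratum not in BMI_STRATA:
            raise CohortValidationError(
                f"bmi_stratum must be one of {BMI_STRATA}, got {self.bmi_stratum!r}",
                [self.patient_id],
            )
        if self.rt_technique not in RT_TECHNIQUES:
            raise CohortValidationError(
                f"rt_technique must be one of {RT_TECHNIQUES}, got {self.rt_technique!r}",
                [self.patient_id],
            )
        if self.local_failure and self.local_failure_time_years is None:
            raise CohortValidationError(
                "local_failure set without local_failure_time_years",
                [self.patient_id],
            )

    @property
    def subgroup(self) -> str:
        """Randomization-cell label, e.g. ``sr_no_bolus`` or ``hr_daily``."""
        prefix = "sr" if self.risk_stratum == "standard" else "hr"
        return f"{prefix}_{self.arm}"


@dataclass(frozen=True)
class VisitSchedule:
    """Planned evaluation weeks, counted from the start of radiotherapy.

    Defaults follow a 28-fraction course: weekly visits through week 5.6
    (the last fraction) and two post-treatment visits at the first and
    third weeks after the end of treatment.
    """

    on_treatment_weeks: Tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 5.6)
    post_treatment_weeks: Tuple[float, ...] = (6.6, 8.6)

    def __post_init__(self):
        object.__setattr__(self, "on_treatment_weeks", tuple(self.on_treatment_weeks))
        object.__setattr__(self, "post_treatment_weeks", tuple(self.post_treatment_weeks))
        allweeks = self.on_treatment_weeks + self.post_treatment_weeks
        if any(b <= a for a, b in zip(allweeks, allweeks[1:])):
            raise ValueError("schedule weeks must be strictly increasing, on-treatment first")

    @property
    def all_weeks(self) -> Tuple[float, ...]:
        return self.on_treatment_weeks + self.post_treatment_weeks

    @property
    def end_of_treatment_week(self) -> float:
        return self.on_treatment_weeks[-1]

    @property
    def end_of_acute_followup_week(self) -> float:
        return self.post_treatment_weeks[-1]


@dataclass(frozen=True)
class TrialCohort:
    patients: Dict[str, Patient]
    trajectories: Dict[str, ToxicityTrajectory]
    schedule: VisitSchedule = field(default_factory=VisitSchedule)

    def __post_init__(self):
        orphans = sorted(set(self.trajectories) - set(self.patients))
        if orphans:
            raise CohortValidationError(
                "trajectories reference unknown patients", orphans
            )
        for pid, traj in self.trajectories.items():
            if traj.patient_id != pid:
                raise CohortValidationError(
                    "trajectory keyed under a different patient_id", [pid]
                )

    def __len__(self) -> int:
        return len(self.patients)

    def subgroup_ids(self, subgroup: str) -> Tuple[str, ...]:
        return tuple(
            pid for pid, p in self.patients.items() if p.subgroup == subgroup
        )

    def arm_ids(self, arm: str) -> Tuple[str, ...]:
        return tuple(pid for pid, p in self.patients.items() if p.arm == arm)


def analysis_populations(
    cohort: TrialCohort,
) -> Tuple[FrozenSet[str], FrozenSet[str]]:
    """Split the cohort into the toxicity and oncologic analysis sets.

    The toxicity set contains every patient with at least one grade
    observation; the oncologic set additionally excludes patients whose
    metastatic disease was detected at or before the start of radiotherapy
    (such patients contribute toxicity data only).
    """
    toxicity = frozenset(
        pid
        for pid in cohort.patients
        if pid in cohort.trajectories and cohort.trajectories[pid].observations
    )
    oncologic = frozenset(
        pid
        for pid in toxicity
        if not cohort.patients[pid].metastasis_at_or_before_rt
    )
    return toxicity, oncologic


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------


def _parse_float(value: str, file, line, fieldname) -> float:
    try:
        return float(value)
    except ValueError:
        raise SchemaError(file, line, fieldname, f"not a number: {value!r}") from None


def _parse_opt_float(value: str, file, line, fieldname) -> Optional[float]:
    if value.strip() == "":
        return None
    return _parse_float(value, file, line, fieldname)


def _parse_int(value: str, file, line, fieldname) -> int:
    try:
        return int(value)
    except ValueError:
        raise SchemaError(file, line, fieldname, f"not an integer: {value!r}") from None


def _parse_bool(value: str, file, line, fieldname) -> bool:
    if value not in ("0", "1"):
        raise SchemaError(file, line, fieldname, f"expected 0 or 1, got {value!r}")
    return value == "1"


def _parse_enum(value: str, allowed, file, line, fieldname) -> str:
    if value not in allowed:
        raise SchemaError(
            file, line, fieldname, f"expected one of {allowed}, got {value!r}"
        )
    return value


def read_cohort(
    patients_path,
    toxicity_path,
    schedule: Optional[VisitSchedule] = None,
    require_observations: bool = True,
) -> TrialCohort:
    """Read and validate a cohort from the two delimited-text files.

    Malformed cells raise :class:`SchemaError` naming file, line and field;
    cross-record invariant violations raise :class:`CohortValidationError`
    listing the offending patients. With ``require_observations`` (default),
    a patient present in the patients file but absent from the toxicity file
    is a validation error.
    """
    patients: Dict[str, Patient] = {}
    with open(patients_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(PATIENT_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise SchemaError(
                patients_path, 1, ",".join(sorted(missing)), "missing column(s)"
            )
        for lineno, row in enumerate(reader, start=2):
            pid = (row["patient_id"] or "").strip()
            if not pid:
                raise SchemaError(patients_path, lineno, "patient_id", "empty id")
            if pid in patients:
                raise SchemaError(
                    patients_path, lineno, "patient_id", f"duplicate id {pid!r}"
                )
            p = Patient(
                patient_id=pid,
                risk_stratum=_parse_enum(
                    row["risk_stratum"], RISK_STRATA, patients_path, lineno, "risk_stratum"
                ),
                arm=_parse_enum(row["arm"], ARMS, patients_path, lineno, "arm"),
                bmi_stratum=_parse_enum(
                    row["bmi_stratum"], BMI_STRATA, patients_path, lineno, "bmi_stratum"
                ),
                age_years=_parse_float(row["age_years"], patients_path, lineno, "age_years"),
                diabetes=_parse_bool(row["diabetes"], patients_path, lineno, "diabetes"),
                smoking_ever=_parse_bool(
                    row["smoking_ever"], patients_path, lineno, "smoking_ever"
                ),
                rt_technique=_parse_enum(
                    row["rt_technique"], RT_TECHNIQUES, patients_path, lineno, "rt_technique"
                ),
                local_failure=_parse_bool(
                    row["local_failure"], patients_path, lineno, "local_failure"
                ),
                local_failure_time_years=_parse_opt_float(
                    row["local_failure_time_years"],
                    patients_path,
                    lineno,
                    "local_failure_time_years",
                ),
                followup_years=_parse_float(
                    row["followup_years"], patients_path, lineno, "followup_years"
                ),
                metastasis_at_or_before_rt=_parse_bool(
                    row["metastasis_at_or_before_rt"],
                    patients_path,
                    lineno,
                    "metastasis_at_or_before_rt",
                ),
            )
            patients[pid] = p

    obs: Dict[str, list] = {}
    stop_week: Dict[str, float] = {}
    with open(toxicity_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(TOXICITY_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise SchemaError(
                toxicity_path, 1, ",".join(sorted(missing)), "missing column(s)"
            )
        for lineno, row in enumerate(reader, start=2):
            pid = (row["patient_id"] or "").strip()
            if pid not in patients:
                raise SchemaError(
                    toxicity_path, lineno, "patient_id", f"unknown patient {pid!r}"
                )
            week = _parse_float(row["week"], toxicity_path, lineno, "week")
            grade = _parse_int(row["grade"], toxicity_path, lineno, "grade")
            if not 0 <= grade <= MAX_GRADE:
                raise SchemaError(
                    toxicity_path, lineno, "grade", f"grade out of range 0..{MAX_GRADE}: {grade}"
                )
            kind = _parse_enum(
                row["visit_kind"], VISIT_KINDS, toxicity_path, lineno, "visit_kind"
            )
            if week <= 0:
                raise SchemaError(toxicity_path, lineno, "week", f"week must be > 0: {week}")
            stopped = _parse_bool(
                row["bolus_stopped"], toxicity_path, lineno, "bolus_stopped"
            )
            if stopped:
                if pid in stop_week:
                    raise SchemaError(
                        toxicity_path, lineno, "bolus_stopped",
                        f"bolus_stopped flagged more than once for {pid!r}",
                    )
                stop_week[pid] = week
            obs.setdefault(pid, []).append(GradeObservation(week, grade, kind))

    trajectories = {}
    for pid, observations in obs.items():
        observations.sort(key=lambda o: o.week)
        trajectories[pid] = ToxicityTrajectory(
            patient_id=pid,
            observations=tuple(observations),
            bolus_stopped_week=stop_week.get(pid),
        )

    if require_observations:
        unobserved = sorted(set(patients) - set(trajectories))
        if unobserved:
            raise CohortValidationError(
                "patients without any toxicity observation", unobserved
            )

    return TrialCohort(
        patients=patients,
        trajectories=trajectories,
        schedule=schedule or VisitSchedule(),
    )


def _fmt_opt(value) -> str:
    return "" if value is None else str(value)


def write_cohort(cohort: TrialCohort, out_dir) -> Tuple[Path, Path]:
    """Write the two cohort files; inverse of :func:`read_cohort`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients_path = out / "patients.csv"
    toxicity_path = out / "toxicity.csv"

    with open(patients_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PATIENT_COLUMNS)
        for p in cohort.patients.values():
            writer.writerow(
                [
                    p.patient_id,
                    p.risk_stratum,
                    p.arm,
                    p.bmi_stratum,
                    str(p.age_years),
                    int(p.diabetes),
                    int(p.smoking_ever),
                    p.rt_technique,
                    int(p.local_failure),
                    _fmt_opt(p.local_failure_time_years),
                    str(p.followup_years),
                    int(p.metastasis_at_or_before_rt),
                ]
            )

    with open(toxicity_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TOXICITY_COLUMNS)
        for pid in cohort.patients:
            traj = cohort.trajectories.get(pid)
            if traj is None:
                continue
            for o in traj.observations:
                stopped = int(
                    traj.bolus_stopped_week is not None
                    and o.week == traj.bolus_stopped_week
                )
                writer.writerow([pid, str(o.week), o.grade, o.visit_kind, stopped])

    return patients_path, toxicity_path
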