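"""Synthetic trial cohorts with the design structure the analysis assumes.

No patient-level data from the trial are available, so this module
generates cohorts that emulate its design: two risk strata (skin-negative
"standard", skin-positive "high"), permuted-block randomization balanced on
the obesity stratum within each risk stratum, weekly ordinal grade
trajectories driven by a monotone Markov step chain whose default
probabilities are calibrated against the printed landmark incidences
(:mod:`radstox.calibrate`), protocol-mandated bolus discontinuation upon a
grade-3 event, and exponential local-failure times anchored to the printed
5-year control rates with administrative censoring around the reported
median follow-up.

Every random quantity flows from one master seed; each patient owns a seed
stream derived from (master seed, patient index), so enlarging a cohort
never perturbs the patients already simulated.

Also provided: a deterministic 51-patient fixture cohort whose per-arm
grade landmark counts equal the trial's printed incidences exactly, and
two small two-group generators with known probabilistic index / relative
risk for parameter-recovery studies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy import stats

from .calibrate import default_progression
from .cohort import (
    ARM_MENU,
    GradeObservation,
    Patient,
    ToxicityTrajectory,
    TrialCohort,
    VisitSchedule,
)

ProgressionTable = Dict[str, Dict[str, Tuple[float, float, float]]]

SUBGROUPS = ("sr_no_bolus", "sr_alternate", "hr_alternate", "hr_daily")


@dataclass(frozen=True)
class SimulationConfig:
    """Trial-design parameters for the synthetic cohort generator.

    Defaults reproduce the study conditions: 32 standard-risk and 19
    high-risk patients, obesity prevalence 35.3%, covariate marginals from
    the baseline table (diabetes 13.7%, ever-smoking 31.4%, CT planning
    58.8%, age ~ N(50, 10) truncated to 25-85), 5-year local control 95.8%
    (standard) / 91.7% (high), median follow-up 6.2 years, and progression
    probabilities calibrated to the printed toxicity incidences. Covariates
    carry no toxicity effect by default; they exist for confounding
    experiments.
    """

    n_standard: int = 32
    n_high: int = 19
    block_size: int = 2
    obesity_prob: float = 0.353
    age_mean: float = 50.0
    age_sd: float = 10.0
    age_min: float = 25.0
    age_max: float = 85.0
    diabetes_prob: float = 0.137
    smoking_prob: float = 0.314
    ct_planning_prob: float = 0.588
    metastasis_prob_standard: float = 0.0
    metastasis_prob_high: float = 0.158
    discontinuation_multiplier: float = 1.0
    local_control_5yr_standard: float = 0.958
    local_control_5yr_high: float = 0.917
    followup_median_years: float = 6.2
    followup_half_range_years: float = 1.0
    progression: Optional[ProgressionTable] = None
    schedule: VisitSchedule = field(default_factory=VisitSchedule)

    def __post_init__(self):
        for name in (
            "obesity_prob",
            "diabetes_prob",
            "smoking_prob",
            "ct_planning_prob",
            "metastasis_prob_standard",
            "metastasis_prob_high",
            "local_control_5yr_standard",
            "local_control_5yr_high",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.block_size < 2 or self.block_size % 2:
            raise ValueError("block_size must be a positive even number")
        if self.progression is not None:
            for sub, cols in self.progression.items():
                if sub not in SUBGROUPS:
                    raise ValueError(f"unknown progression subgroup {sub!r}")
                for phase in ("on", "post"):
                    probs = cols[phase]
                    if len(probs) != 3 or any(not 0 <= p <= 1 for p in probs):
                        raise ValueError(
                            f"progression[{sub}][{phase}] must be three "
                            f"probabilities in [0, 1]"
                        )

    def resolved(self) -> "SimulationConfig":
        """Fill the progression table with calibrated defaults if unset."""
        if self.progression is not None:
            return self
        prog = default_progression(
            n_on=len(self.schedule.on_treatment_weeks),
            n_post=len(self.schedule.post_treatment_weeks),
        )
        return dataclasses.replace(self, progression=prog)


_CONFIG_SCALARS = [
    f.name
    for f in dataclasses.fields(SimulationConfig)
    if f.name not in ("progression", "schedule")
]


def config_to_yaml(config: SimulationConfig, path) -> Path:
    """Write the resolved configuration as flat key-value text."""
    config = config.resolved()
    data = {name: getattr(config, name) for name in _CONFIG_SCALARS}
    data["on_treatment_weeks"] = list(config.schedule.on_treatment_weeks)
    data["post_treatment_weeks"] = list(config.schedule.post_treatment_weeks)
    for sub, cols in config.progression.items():
        for phase in ("on", "post"):
            data[f"progression_{sub}_{phase}"] = [float(p) for p in cols[phase]]
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, default_flow_style=None, sort_keys=True)
    return path


def config_from_yaml(path) -> SimulationConfig:
    """Read a flat key-value configuration; unknown keys are an error."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    kwargs = {}
    progression: ProgressionTable = {}
    schedule_kw = {}
    for key, value in data.items():
        if key in _CONFIG_SCALARS:
            kwargs[key] = value
        elif key in ("on_treatment_weeks", "post_treatment_weeks"):
            schedule_kw[key] = tuple(float(v) for v in value)
        elif key.startswith("progression_"):
            rest = key[len("progression_"):]
            sub, _, phase = rest.rpartition("_")
            if sub not in SUBGROUPS or phase not in ("on", "post"):
                raise ValueError(f"unknown config key {key!r}")
            progression.setdefault(sub, {})[phase] = tuple(float(v) for v in value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    if progression:
        missing = [
            f"progression_{s}_{ph}"
            for s in SUBGROUPS
            for ph in ("on", "post")
            if ph not in progression.get(s, {})
        ]
        if missing:
            raise ValueError(
                "incomplete progression table; missing keys: " + ", ".join(missing)
            )
        kwargs["progression"] = progression
    if schedule_kw:
        kwargs["schedule"] = VisitSchedule(**schedule_kw)
    return SimulationConfig(**kwargs)


# ---------------------------------------------------------------------------
# Randomization
# ---------------------------------------------------------------------------


def stratified_randomize(
    patients: Sequence[Tuple[str, str, str]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Dict[str, str]:
    """Permuted-block assignment within (risk stratum x BMI stratum) cells.

    ``patients`` is a sequence of (patient_id, risk_stratum, bmi_stratum).
    Each stratum draws from its own two-arm menu; within any cell, arm
    counts never differ by more than the block size. Every possible cell
    owns an independent stream spawned from ``rng`` in a fixed order, so
    enrolling additional patients into one cell never perturbs the block
    sequences of the others.
    """
    all_cells = [
        (stratum, bmi) for stratum in ("standard", "high") for bmi in ("lt30", "ge30")
    ]
    cell_rngs = dict(zip(all_cells, rng.spawn(len(all_cells))))
    cells: Dict[Tuple[str, str], List[str]] = {}
    for pid, stratum, bmi in patients:
        cells.setdefault((stratum, bmi), []).append(pid)
    assignment: Dict[str, str] = {}
    for (stratum, bmi), ids in sorted(cells.items()):
        cell_rng = cell_rngs[(stratum, bmi)]
        arms = ARM_MENU[stratum]
        per_arm = config.block_size // len(arms)
        block = [arm for arm in arms for _ in range(per_arm)]
        sequence: List[str] = []
        while len(sequence) < len(ids):
            sequence.extend(cell_rng.permutation(block).tolist())
        for pid, arm in zip(ids, sequence):
            assignment[pid] = arm
    return assignment


# ---------------------------------------------------------------------------
# Toxicity trajectories
# ---------------------------------------------------------------------------


def simulate_toxicity(
    subgroup: str,
    arm: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    patient_id: str = "",
) -> ToxicityTrajectory:
    """One weekly grade trajectory from the monotone step chain.

    At each visit the grade steps +1 with the subgroup-, grade- and
    phase-specific probability, else stays. Upon first reaching grade 3 at
    an on-treatment visit of a bolus arm, the bolus is discontinued and
    subsequent step probabilities switch to the no-bolus column scaled by
    the discontinuation multiplier. Grade 3 is terminal by default (no
    grade-4 step probability is modeled; none occurred in the trial).
    """
    config = config.resolved()
    prog = config.progression[subgroup]
    nobolus = config.progression["sr_no_bolus"]
    schedule = config.schedule
    grade = 0
    stopped_week: Optional[float] = None
    observations = []
    for kind, weeks in (
        ("on_treatment", schedule.on_treatment_weeks),
        ("post_treatment", schedule.post_treatment_weeks),
    ):
        for week in weeks:
            if grade < 3:
                if stopped_week is None:
                    p = prog["on" if kind == "on_treatment" else "post"][grade]
                else:
                    base = nobolus["on" if kind == "on_treatment" else "post"][grade]
                    p = min(1.0, base * config.discontinuation_multiplier)
                if rng.random() < p:
                    grade += 1
            if (
                grade >= 3
                and stopped_week is None
                and kind == "on_treatment"
                and arm != "no_bolus"
            ):
                stopped_week = week
            observations.append(GradeObservation(week, grade, kind))
    return ToxicityTrajectory(
        patient_id=patient_id,
        observations=tuple(observations),
        bolus_stopped_week=stopped_week,
    )


# ---------------------------------------------------------------------------
# Oncologic outcomes
# ---------------------------------------------------------------------------


def simulate_oncologic(
    stratum: str, config: SimulationConfig, rng: np.random.Generator
) -> Dict[str, object]:
    """Local-failure time and administrative censoring for one patient.

    Failure times are exponential with rate -ln(C5)/5 where C5 is the
    stratum's 5-year local-control probability; censoring is uniform in
    a window around the configured median follow-up.
    """
    c5 = (
        config.local_control_5yr_standard
        if stratum == "standard"
        else config.local_control_5yr_high
    )
    censor = rng.uniform(
        config.followup_median_years - config.followup_half_range_years,
        config.followup_median_years + config.followup_half_range_years,
    )
    if c5 >= 1.0:
        t_fail = np.inf
    else:
        lam = -np.log(c5) / 5.0
        t_fail = rng.exponential(1.0 / lam)
    failed = bool(t_fail <= censor)
    return {
        "local_failure": failed,
        "local_failure_time_years": float(t_fail) if failed else None,
        "followup_years": float(min(t_fail, censor)),
    }


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mean, lo), hi))


def simulate_cohort(config: SimulationConfig, seed: int) -> TrialCohort:
    """A full synthetic cohort under the configured trial design."""
    config = config.resolved()
    if config.n_standard + config.n_high == 0:
        raise ValueError("cannot simulate an empty cohort")
    spec: List[Tuple[str, str]] = [
        (f"S{k + 1:03d}", "standard") for k in range(config.n_standard)
    ] + [(f"H{k + 1:03d}", "high") for k in range(config.n_high)]

    # patient-level streams keyed by position; cohort-level stream for the
    # randomization lists
    streams = {
        pid: np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(idx,)))
        for idx, (pid, _) in enumerate(spec)
    }
    rand_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10**6,)))

    base: Dict[str, Dict[str, object]] = {}
    for pid, stratum in spec:
        rng = streams[pid]
        base[pid] = {
            "stratum": stratum,
            "bmi": "ge30" if rng.random() < config.obesity_prob else "lt30",
            "age": _truncated_normal(
                rng, config.age_mean, config.age_sd, config.age_min, config.age_max
            ),
            "diabetes": bool(rng.random() < config.diabetes_prob),
            "smoking": bool(rng.random() < config.smoking_prob),
            "rt": "ct_planned"
            if rng.random() < config.ct_planning_prob
            else "conventional",
            "metastasis": bool(
                rng.random()
                < (
                    config.metastasis_prob_standard
                    if stratum == "standard"
                    else config.metastasis_prob_high
                )
            ),
        }

    assignment = stratified_randomize(
        [(pid, b["stratum"], b["bmi"]) for pid, b in base.items()], config, rand_rng
    )

    patients: Dict[str, Patient] = {}
    trajectories: Dict[str, ToxicityTrajectory] = {}
    for pid, stratum in spec:
        b = base[pid]
        arm = assignment[pid]
        prefix = "sr" if stratum == "standard" else "hr"
        subgroup = f"{prefix}_{arm}"
        rng = streams[pid]
        trajectories[pid] = simulate_toxicity(
            subgroup, arm, config, rng, patient_id=pid
        )
        outcome = simulate_oncologic(stratum, config, rng)
        patients[pid] = Patient(
            patient_id=pid,
            risk_stratum=stratum,
            arm=arm,
            bmi_stratum=b["bmi"],
            age_years=round(float(b["age"]), 1),
            diabetes=b["diabetes"],
            smoking_ever=b["smoking"],
            rt_technique=b["rt"],
            local_failure=outcome["local_failure"],
            local_failure_time_years=outcome["local_failure_time_years"],
            followup_years=outcome["followup_years"],
            metastasis_at_or_before_rt=b["metastasis"],
        )
    return TrialCohort(
        patients=patients, trajectories=trajectories, schedule=config.schedule
    )


# ---------------------------------------------------------------------------
# Deterministic fixture cohort from the printed counts
# ---------------------------------------------------------------------------


def _spread_flags(n: int, k: int, offset: int = 0) -> List[bool]:
    """k of n flags, evenly interleaved (deterministic, order-stable)."""
    return [((i + offset) * k) // n != ((i + offset + 1) * k) // n for i in range(n)]


def _grade_path(
    schedule: VisitSchedule,
    g1_at: Optional[float],
    g2_at: Optional[float] = None,
    g3_at: Optional[float] = None,
) -> Tuple[GradeObservation, ...]:
    """Monotone grade path reaching each level at the given visit week."""
    onsets = [(3, g3_at), (2, g2_at), (1, g1_at)]
    obs = []
    for kind, weeks in (
        ("on_treatment", schedule.on_treatment_weeks),
        ("post_treatment", schedule.post_treatment_weeks),
    ):
        for week in weeks:
            grade = 0
            for level, onset in onsets:
                if onset is not None and week >= onset:
                    grade = level
                    break
            obs.append(GradeObservation(week, grade, kind))
    return tuple(obs)


# per-arm trajectory plans: (g1_at, g2_at, g3_at) visit weeks; None = never.
# Counts reproduce the printed incidences: G2 at end of RT 5/15, 4/17, 4/9,
# 10/10; G3 by end of acute follow-up 0, 0, 1/9, 7/10; every patient reaches
# G1; five of the eight G3 onsets fall at post-treatment visits; the three
# on-treatment G3 events (one alternate, two daily, all high-risk) occur in
# the last treatment week with bolus discontinued there.
_FIXTURE_PLAN: Dict[str, List[Tuple[Optional[float], Optional[float], Optional[float]]]] = {
    "sr_no_bolus": [
        (1, None, None), (2, None, None), (3, None, None), (4, None, None),
        (5, None, None), (2, None, None), (3, None, None), (4, None, None),
        (1, None, None), (5, None, None),
        (1, 2, None), (2, 4, None), (1, 5, None), (2, 5, None), (3, 5.6, None),
    ],
    "sr_alternate": [
        (1, None, None), (2, None, None), (3, None, None), (4, None, None),
        (5, None, None), (1, None, None), (2, None, None), (3, None, None),
        (4, None, None), (5, None, None), (2, None, None), (3, None, None),
        (1, None, None),
        (1, 4, None), (2, 5, None), (3, 5.6, None), (1, 3, None),
    ],
    "hr_alternate": [
        (1, None, None), (2, None, None), (3, None, None), (4, None, None),
        (5, None, None),
        (1, 3, None), (2, 5, None), (3, 5.6, None),
        (2, 4, 5.6),
    ],
    "hr_daily": [
        (5, 5.6, None), (3, 5.6, None), (2, 4, None),
        (1, 3, 5.6), (2, 4, 5.6),
        (1, 3, 6.6), (2, 4, 6.6), (1, 4, 6.6),
        (2, 5, 8.6), (1, 5, 8.6),
    ],
}

_FIXTURE_COVARIATES = {
    # subgroup: (n_ge30, n_diabetes, n_smoking, n_conventional, n_age_gt50)
    "sr_no_bolus": (5, 0, 4, 7, 7),
    "sr_alternate": (6, 3, 7, 5, 9),
    "hr_alternate": (4, 1, 2, 4, 5),
    "hr_daily": (3, 3, 3, 5, 4),
}

#: (failure index, failure time years) per subgroup, plus metastasis indices
_FIXTURE_FAILURES = {
    "sr_no_bolus": (0, 2.0),
    "sr_alternate": (0, 3.0),
    "hr_alternate": (1, 1.5),
    "hr_daily": (1, 4.0),
}
_FIXTURE_METASTASIS = {"hr_alternate": (0,), "hr_daily": (3, 4)}
_FIXTURE_FOLLOWUP_YEARS = 6.2


def fixture_cohort_from_printed_counts() -> TrialCohort:
    """The deterministic 51-patient cohort matching the printed incidences.

    Per-arm counts of patients reaching grade >= 1/2/3 at the reporting
    landmarks equal the published percentages exactly; every patient is
    observed at all eight scheduled visits (no censoring before the end of
    acute follow-up), so Kaplan-Meier landmark estimates coincide with the
    crude proportions.
    """
    schedule = VisitSchedule()
    patients: Dict[str, Patient] = {}
    trajectories: Dict[str, ToxicityTrajectory] = {}
    counter = 0
    for subgroup in SUBGROUPS:
        plan = _FIXTURE_PLAN[subgroup]
        stratum = "standard" if subgroup.startswith("sr") else "high"
        arm = subgroup.split("_", 1)[1]
        n = len(plan)
        n_ge30, n_dm, n_smoke, n_conv, n_old = _FIXTURE_COVARIATES[subgroup]
        ge30 = _spread_flags(n, n_ge30, offset=0)
        dm = _spread_flags(n, n_dm, offset=1)
        smoke = _spread_flags(n, n_smoke, offset=2)
        conv = _spread_flags(n, n_conv, offset=3)
        old = _spread_flags(n, n_old, offset=4)
        fail_idx, fail_time = _FIXTURE_FAILURES[subgroup]
        met_idx = set(_FIXTURE_METASTASIS.get(subgroup, ()))
        for i, (g1_at, g2_at, g3_at) in enumerate(plan):
            counter += 1
            pid = f"P{counter:02d}"
            obs = _grade_path(schedule, g1_at, g2_at, g3_at)
            stopped = None
            if (
                g3_at is not None
                and g3_at <= schedule.end_of_treatment_week
                and arm != "no_bolus"
            ):
                stopped = g3_at
            trajectories[pid] = ToxicityTrajectory(
                patient_id=pid, observations=obs, bolus_stopped_week=stopped
            )
            failed = i == fail_idx
            patients[pid] = Patient(
                patient_id=pid,
                risk_stratum=stratum,
                arm=arm,
                bmi_stratum="ge30" if ge30[i] else "lt30",
                age_years=float(55 + (i % 10)) if old[i] else float(40 + (i % 10)),
                diabetes=dm[i],
                smoking_ever=smoke[i],
                rt_technique="conventional" if conv[i] else "ct_planned",
                local_failure=failed,
                local_failure_time_years=fail_time if failed else None,
                followup_years=_FIXTURE_FOLLOWUP_YEARS,
                metastasis_at_or_before_rt=i in met_idx,
            )
    return TrialCohort(patients=patients, trajectories=trajectories, schedule=schedule)


# ---------------------------------------------------------------------------
# Two-group generators with known truth, for parameter-recovery studies
# ---------------------------------------------------------------------------


def simulate_scores_two_group(
    n_per_group: int, true_pi: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Continuous scores whose placement probability is exactly ``true_pi``.

    Both groups are unit normals; the treated group is shifted by
    sqrt(2) * Phi^-1(PI), for which P(Y_ref < Y_trt) = PI in closed form.
    """
    if not 0.0 < true_pi < 1.0:
        raise ValueError("true_pi must lie strictly inside (0, 1)")
    delta = np.sqrt(2.0) * stats.norm.ppf(true_pi)
    ref = rng.normal(0.0, 1.0, size=n_per_group)
    trt = rng.normal(delta, 1.0, size=n_per_group)
    return ref, trt


def simulate_binary_two_group(
    n_per_group: int, p_ref: float, true_rr: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Binary outcomes with event probability p_ref and p_ref * true_rr.

    Returns (outcome, group indicator) stacked reference-first.
    """
    p_trt = p_ref * true_rr
    if not (0.0 < p_ref < 1.0 and 0.0 < p_trt < 1.0):
        raise ValueError("event probabilities must lie strictly inside (0, 1)")
    y = np.concatenate(
        [
            (rng.random(n_per_group) < p_ref).astype(float),
            (rng.random(n_per_group) < p_trt).astype(float),
        ]
    )
    x = np.concatenate([np.zeros(n_per_group), np.ones(n_per_group)])
    return y, x
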