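"""The radiodermatitis toxicity index (rads-TI).

A patient's weekly grade sequence g_1, ..., g_n is summarized by a single
scalar that (i) has integer part equal to the maximum grade, (ii) strictly
increases with any additional positive-grade week, yet (iii) never lets
repeated events of one grade overtake a single event of the next higher
grade, and (iv) preserves the ranking of patients whose sorted grade
sequences are ordered element-wise. With the grades sorted non-increasingly
g(1) >= g(2) >= ... >= g(n), the index is the series

    TI = sum_i g(i) / prod_{j<i} (1 + g(j)).

Each successive term is divided by the running product of (1 + grade) of
all larger terms, so the whole tail beyond position i contributes strictly
less than one unit of the grade at position i. Zero grades add nothing and
leave the running product unchanged, so trailing grade-0 weeks never alter
a score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Set

import pandas as pd

from .cohort import MAX_GRADE, TrialCohort
from .exceptions import CohortValidationError

#: Two scores within this distance are treated as equal by reporting code.
#: The index is an exact rational; float evaluation of <= 9 terms keeps far
#: more than 12 significant digits.
TI_TOLERANCE = 1e-12


@dataclass(frozen=True)
class ToxicityScore:
    patient_id: str
    ti: float
    max_grade: int
    n_observations: int


def toxicity_index(grades: Sequence[int]) -> float:
    """Score a sequence of integer grades 0-4; order-invariant.

    Raises ``ValueError`` on an empty sequence or out-of-range grade.
    """
    grades = list(grades)
    if not grades:
        raise ValueError("toxicity_index requires at least one grade")
    for g in grades:
        if not (isinstance(g, (int,)) and 0 <= g <= MAX_GRADE):
            raise ValueError(f"grade must be an integer in 0..{MAX_GRADE}, got {g!r}")
    ti = 0.0
    denom = 1.0
    for g in sorted(grades, reverse=True):
        if g == 0:
            break  # zeros contribute nothing and do not grow the product
        ti += g / denom
        denom *= 1 + g
    return ti


def score_cohort(
    cohort: TrialCohort,
    population: Optional[Iterable[str]] = None,
    include_post_treatment: bool = True,
) -> List[ToxicityScore]:
    """Compute one :class:`ToxicityScore` per patient in ``population``.

    By default all observations enter the score: grade-3 events commonly
    first appear at the post-treatment visits, and the index is meant to
    cover the whole course. Pass ``include_post_treatment=False`` to score
    the on-treatment window only.

    Results follow the cohort's patient order (deterministic).
    """
    if population is None:
        population = [pid for pid in cohort.patients if pid in cohort.trajectories]
    else:
        population_set: Set[str] = set(population)
        unknown = sorted(population_set - set(cohort.patients))
        if unknown:
            raise CohortValidationError("patient has no toxicity trajectory", unknown)
        population = [pid for pid in cohort.patients if pid in population_set]

    scores = []
    for pid in population:
        traj = cohort.trajectories.get(pid)
        if traj is None or not traj.observations:
            raise CohortValidationError("patient has no toxicity trajectory", [pid])
        obs = traj.observations
        if not include_post_treatment:
            obs = tuple(o for o in obs if o.visit_kind == "on_treatment")
            if not obs:
                raise CohortValidationError(
                    "patient has no on-treatment observations", [pid]
                )
        grades = [o.grade for o in obs]
        scores.append(
            ToxicityScore(
                patient_id=pid,
                ti=toxicity_index(grades),
                max_grade=max(grades),
                n_observations=len(grades),
            )
        )
    return scores


def scores_frame(scores: Sequence[ToxicityScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in scores],
            "rads_ti": [s.ti for s in scores],
            "max_grade": [s.max_grade for s in scores],
            "n_observations": [s.n_observations for s in scores],
        }
    )


def write_scores(scores: Sequence[ToxicityScore], path) -> Path:
    path = Path(path)
    scores_frame(scores).to_csv(path, index=False)
    return path
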