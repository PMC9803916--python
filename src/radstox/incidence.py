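"""Grade-onset incidence curves and exact 2x2 testing.

Onset of grade >= g is interval-censored between weekly visits; the visit
week at which the threshold is first met serves as the event time (right
endpoint of the interval). Patients who never reach the threshold are
censored at their last visit. Incidence P(onset <= t) is estimated by the
Kaplan-Meier product-limit method (via lifelines); subgroup contrasts of
landmark proportions use Fisher's exact test with the point-probability
two-sided convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .cohort import ToxicityTrajectory, TrialCohort


def first_exceedance_week(traj: ToxicityTrajectory, g: int) -> Optional[float]:
    """Smallest observed week with grade >= g, or None if never reached."""
    if not 1 <= g <= 4:
        raise ValueError(f"grade threshold must be in 1..4, got {g}")
    for obs in traj.observations:
        if obs.grade >= g:
            return obs.week
    return None


@dataclass(frozen=True)
class IncidenceCurve:
    """Step function for cumulative incidence of grade >= ``grade_threshold``."""

    grade_threshold: int
    label: str
    times: np.ndarray  # starts at 0
    cumulative_incidence: np.ndarray
    n_at_risk: np.ndarray

    def incidence_at(self, week: float) -> float:
        """Right-continuous step lookup: value at the last time <= ``week``."""
        idx = np.searchsorted(self.times, week, side="right") - 1
        if idx < 0:
            return 0.0
        return float(self.cumulative_incidence[idx])


def km_incidence(
    cohort: TrialCohort,
    subgroup: Iterable[str],
    g: int,
    label: Optional[str] = None,
) -> IncidenceCurve:
    """Kaplan-Meier cumulative incidence of first grade >= g in ``subgroup``.

    With no censoring before the horizon the curve at the horizon equals
    the crude proportion of patients with onset by then.
    """
    ids = sorted(subgroup)
    if not ids:
        raise ValueError("km_incidence requires a nonempty subgroup")
    durations, events = [], []
    for pid in ids:
        traj = cohort.trajectories[pid]
        onset = first_exceedance_week(traj, g)
        if onset is None:
            durations.append(traj.last_week)
            events.append(0)
        else:
            durations.append(onset)
            events.append(1)

    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    table = kmf.event_table
    times = np.asarray(table.index, dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    if times.size == 0 or times[0] > 0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
        at_risk = np.concatenate([[float(len(ids))], at_risk])
    return IncidenceCurve(
        grade_threshold=g,
        label=label if label is not None else "",
        times=times,
        cumulative_incidence=1.0 - surv,
        n_at_risk=at_risk,
    )


def landmark_counts(
    cohort: TrialCohort, subgroup: Iterable[str], g: int, landmark_week: float
) -> Tuple[int, int]:
    """(events, total): patients with grade >= g onset at or before the landmark."""
    ids = sorted(subgroup)
    events = 0
    for pid in ids:
        onset = first_exceedance_week(cohort.trajectories[pid], g)
        if onset is not None and onset <= landmark_week:
            events += 1
    return events, len(ids)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    The two-sided p sums hypergeometric probabilities of every table with
    the same margins whose probability does not exceed that of the observed
    table (point-probability ordering, the convention of R's fisher.test).
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if not (isinstance(v, (int, np.integer)) and v >= 0):
            raise ValueError(f"table entry {name} must be a non-negative integer, got {v!r}")
    if a + b + c + d == 0:
        raise ValueError("at least one table margin must be positive")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)


def incidence_frame(curves: Iterable[IncidenceCurve]) -> pd.DataFrame:
    rows = []
    for curve in curves:
        for t, n, inc in zip(curve.times, curve.n_at_risk, curve.cumulative_incidence):
            rows.append(
                {
                    "subgroup": curve.label,
                    "grade_threshold": curve.grade_threshold,
                    "week": t,
                    "n_at_risk": n,
                    "cumulative_incidence": inc,
                }
            )
    return pd.DataFrame(rows)
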