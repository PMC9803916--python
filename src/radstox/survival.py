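"""Kaplan-Meier estimation and log-rank testing for oncologic endpoints.

Time origin is the start of radiotherapy for every endpoint, matching the
toxicity convention. Curves are product-limit estimates with Greenwood
variance; when events and censorings coincide, events precede censorings
in the risk set. Estimation rides on lifelines; this module fixes the
conventions and exposes a plain step-function container.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous survival step function with Greenwood variance."""

    label: str
    times: np.ndarray  # starts at 0
    survival: np.ndarray
    greenwood_var: np.ndarray
    n_at_risk: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        """S at the last step time <= t (the value just after any event at t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    def greenwood_se_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(np.sqrt(self.greenwood_var[max(idx, 0)]))


def km_curve(
    times: Sequence[float], events: Sequence[int], label: str = ""
) -> SurvivalCurve:
    """Product-limit estimate from follow-up times and 0/1 event flags."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t < 0):
        raise ValueError("negative follow-up time")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event flags must be 0/1")

    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    grid = np.asarray(table.index, dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=float)
    d = table["observed"].to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    # Greenwood: var(t) = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(d > 0, d / (at_risk * (at_risk - d)), 0.0)
    inc = np.where(np.isfinite(inc), inc, 0.0)
    gw = surv**2 * np.cumsum(inc)

    if grid.size == 0 or grid[0] > 0:
        grid = np.concatenate([[0.0], grid])
        surv = np.concatenate([[1.0], surv])
        gw = np.concatenate([[0.0], gw])
        at_risk = np.concatenate([[float(t.shape[0])], at_risk])
    return SurvivalCurve(
        label=label,
        times=grid,
        survival=surv,
        greenwood_var=gw,
        n_at_risk=at_risk,
        censor_times=np.sort(t[e == 0]),
    )


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.chi_square, self.p_value))


def logrank(groups: Sequence[Tuple[Sequence[float], Sequence[int]]]) -> LogrankResult:
    """Log-rank test across k >= 2 groups of (times, events).

    With no events anywhere the statistic is degenerate: 0 with p = 1,
    flagged as such.
    """
    if len(groups) < 2:
        raise ValueError("logrank requires at least two groups")
    durations, events, labels = [], [], []
    for k, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {k} is empty")
        durations.append(t)
        events.append(e)
        labels.append(np.full(t.shape, k))
    durations = np.concatenate(durations)
    events = np.concatenate(events)
    labels = np.concatenate(labels)
    if events.sum() == 0:
        return LogrankResult(0.0, 1.0, degenerate=True)
    res = multivariate_logrank_test(durations, labels, events)
    return LogrankResult(float(res.test_statistic), float(res.p_value))


def survival_frame(curves: Iterable[SurvivalCurve], endpoint: str) -> pd.DataFrame:
    rows = []
    for curve in curves:
        censored = set(np.round(curve.censor_times, 10))
        for t, n, s, v in zip(
            curve.times, curve.n_at_risk, curve.survival, curve.greenwood_var
        ):
            rows.append(
                {
                    "endpoint": endpoint,
                    "subgroup": curve.label,
                    "time_years": t,
                    "n_risk": n,
                    "survival": s,
                    "greenwood_se": float(np.sqrt(v)),
                    "censored": int(round(t, 10) in censored),
                }
            )
    return pd.DataFrame(rows)
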