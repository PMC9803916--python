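"""Relative risks for binary toxicity endpoints via quasi-Poisson regression.

A log-link Poisson regression on a 0/1 endpoint returns coefficients that
exponentiate to relative risks (not odds ratios). Because a binary outcome
is under-dispersed relative to Poisson, the covariance is rescaled by the
Pearson dispersion

    phi = (1 / (n - p)) * sum (y_i - mu_i)^2 / mu_i,

and Wald 95% intervals are formed on the log scale, exp(coef +/- 1.96 se).
For a saturated group-indicator model the fitted means equal the observed
group event proportions exactly, so the group RR is the plain ratio of
proportions with a dispersion-robust interval.

Estimation is delegated to statsmodels' GLM (Poisson family, log link,
``scale='X2'``); this module adds the endpoint construction, boundary
handling for zero-event groups, and a trial-oriented results surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import TrialCohort, analysis_populations
from .exceptions import BoundaryError, RankDeficiencyError
from .incidence import first_exceedance_week

Z_95 = 1.96

#: endpoint name -> (grade threshold, landmark attribute on the schedule)
ENDPOINTS = {
    "G2_at_end_of_rt": (2, "end_of_treatment_week"),
    "G3_any": (3, "end_of_acute_followup_week"),
}

#: covariate name -> extractor on Patient (confounder set of the trial)
ADJUSTERS = {
    "age": lambda p: p.age_years,
    "bmi_ge30": lambda p: float(p.bmi_stratum == "ge30"),
    "diabetes": lambda p: float(p.diabetes),
    "smoking_ever": lambda p: float(p.smoking_ever),
    "ct_planned": lambda p: float(p.rt_technique == "ct_planned"),
}


class RelativeRiskModel:
    """Log-link Poisson model for a binary endpoint; ``fit()`` -> results."""

    def __init__(self, endog, exog, exog_names: Optional[Sequence[str]] = None):
        y = np.asarray(endog, dtype=float)
        if isinstance(exog, pd.DataFrame):
            if exog_names is None:
                exog_names = [str(c) for c in exog.columns]
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            if exog_names is None:
                exog_names = [f"x{k}" for k in range(X.shape[1])]
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("endpoint must be binary 0/1")
        if X.shape[0] != y.shape[0]:
            raise ValueError("endog and exog lengths differ")
        if X.shape[0] <= X.shape[1]:
            raise ValueError("more parameters than observations")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _, r = np.linalg.qr(X)
            diag = np.abs(np.diag(r))
            bad = [exog_names[k] for k in range(X.shape[1]) if diag[k] <= 1e-10 * diag.max()]
            raise RankDeficiencyError(bad or list(exog_names))
        self.endog = y
        self.exog = X
        self.exog_names = tuple(exog_names)

    def fit(self) -> "RelativeRiskResults":
        if self.endog.sum() == 0:
            raise BoundaryError(
                "no events at all: every log-mean diverges; the relative risk "
                "is undefined", self.exog_names
            )
        # a binary indicator column whose stratum has zero events puts the
        # MLE on the boundary (RR -> 0); surface it instead of a huge number
        boundary_terms = []
        for k, name in enumerate(self.exog_names):
            col = self.exog[:, k]
            vals = np.unique(col)
            if set(vals.tolist()) <= {0.0, 1.0} and not np.all(col == 1.0):
                if self.endog[col == 1.0].sum() == 0 and (col == 1.0).any():
                    boundary_terms.append(name)
        if boundary_terms:
            raise BoundaryError(
                "zero events in the stratum of indicator term(s) "
                + ", ".join(boundary_terms)
                + ": the fitted relative risk is on the boundary (0 or "
                "infinite); no finite Wald interval exists",
                boundary_terms,
            )
        glm = sm.GLM(self.endog, self.exog, family=sm.families.Poisson())
        res = glm.fit(scale="X2", maxiter=200, tol=1e-10)
        if not res.converged or np.any(np.abs(res.params) > 20):
            raise BoundaryError(
                "quasi-Poisson fit diverged toward a boundary", self.exog_names
            )
        return RelativeRiskResults(self, res)


class RelativeRiskResults:
    """Coefficients on the log-RR scale with dispersion-scaled Wald inference."""

    def __init__(self, model: RelativeRiskModel, glm_results):
        self.model = model
        self._glm = glm_results
        self.exog_names = model.exog_names
        self.params = pd.Series(glm_results.params, index=self.exog_names)
        self.dispersion = float(glm_results.scale)  # Pearson chi2 / (n - p)
        self.pearson_chi2 = float(glm_results.pearson_chi2)
        self.df_resid = int(glm_results.df_resid)
        self.cov_params = pd.DataFrame(
            glm_results.cov_params(), index=self.exog_names, columns=self.exog_names
        )
        self.bse = pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.exog_names)
        self.fittedvalues = np.asarray(glm_results.fittedvalues)
        self.nobs = int(model.endog.shape[0])

    @property
    def rr(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self) -> pd.DataFrame:
        lo = np.exp(self.params - Z_95 * self.bse)
        hi = np.exp(self.params + Z_95 * self.bse)
        return pd.DataFrame({"ci_lower": lo, "ci_upper": hi})

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=self.exog_names)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Quasi-Poisson relative-risk model (log link)",
            f"n = {self.nobs}   Pearson dispersion = {self.dispersion:.4f} "
            f"(chi2 {self.pearson_chi2:.2f} / df {self.df_resid})",
            f"{'term':<24}{'RR':>10}{'95% CI':>22}{'p':>10}",
        ]
        for name in self.exog_names:
            lines.append(
                f"{name:<24}{self.rr[name]:>10.3f}"
                f"{f'({ci.ci_lower[name]:.3f}, {ci.ci_upper[name]:.3f})':>22}"
                f"{self.pvalues[name]:>10.4g}"
            )
        return "\n".join(lines)


def fit_quasipoisson(
    outcome, design, exog_names: Optional[Sequence[str]] = None
) -> RelativeRiskResults:
    """Functional wrapper: design must already contain its intercept column."""
    return RelativeRiskModel(outcome, design, exog_names).fit()


def endpoint_outcome(
    cohort: TrialCohort, endpoint: str, population: Iterable[str]
) -> pd.Series:
    """0/1 per patient: reached the endpoint's grade by its landmark week."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; options: {sorted(ENDPOINTS)}")
    g, landmark_attr = ENDPOINTS[endpoint]
    landmark = getattr(cohort.schedule, landmark_attr)
    ids = [pid for pid in cohort.patients if pid in set(population)]
    vals = []
    for pid in ids:
        onset = first_exceedance_week(cohort.trajectories[pid], g)
        vals.append(1.0 if (onset is not None and onset <= landmark) else 0.0)
    return pd.Series(vals, index=ids, name=endpoint)


def _arm_design(
    cohort: TrialCohort, ids: Sequence[str], arm_coding: str
) -> pd.DataFrame:
    arms = pd.Series({pid: cohort.patients[pid].arm for pid in ids})
    if arm_coding == "per_arm":
        cols = {
            "alternate": (arms == "alternate").astype(float),
            "daily": (arms == "daily").astype(float),
        }
    elif arm_coding == "daily_vs_pooled":
        cols = {"daily": (arms == "daily").astype(float)}
    else:
        raise ValueError(f"unknown arm_coding {arm_coding!r}")
    out = pd.DataFrame({"intercept": 1.0, **cols}, index=list(ids))
    return out


def adjusted_rr(
    cohort: TrialCohort,
    endpoint: str,
    adjusters: Sequence[str] = (),
    population: Optional[Iterable[str]] = None,
    arm_coding: str = "per_arm",
) -> RelativeRiskResults:
    """Arm relative risks for a landmark toxicity endpoint.

    ``adjusters`` names covariates from :data:`ADJUSTERS`. ``arm_coding``
    is ``per_arm`` (alternate and daily indicators against a no-bolus
    reference) or ``daily_vs_pooled`` (daily against no-bolus and
    alternate combined). With no adjusters the model is saturated in the
    groups and reproduces the crude ratio of event proportions.
    """
    if population is None:
        population, _ = analysis_populations(cohort)
    y = endpoint_outcome(cohort, endpoint, population)
    ids = list(y.index)
    X = _arm_design(cohort, ids, arm_coding)
    for name in adjusters:
        if name not in ADJUSTERS:
            raise ValueError(f"unknown adjuster {name!r}; options: {sorted(ADJUSTERS)}")
        X[name] = [ADJUSTERS[name](cohort.patients[pid]) for pid in ids]
    res = RelativeRiskModel(y.to_numpy(), X).fit()
    return res


def events_by_term(
    cohort: TrialCohort, endpoint: str, population: Iterable[str], arm_coding: str
) -> Dict[str, Tuple[int, int]]:
    """events/total per reported term, mirroring a trial table's counts column."""
    y = endpoint_outcome(cohort, endpoint, population)
    arms = pd.Series({pid: cohort.patients[pid].arm for pid in y.index})
    out: Dict[str, Tuple[int, int]] = {}
    if arm_coding == "per_arm":
        groups = {"no_bolus": arms == "no_bolus", "alternate": arms == "alternate",
                  "daily": arms == "daily"}
    else:
        groups = {"no_or_alternate": arms != "daily", "daily": arms == "daily"}
    for name, mask in groups.items():
        out[name] = (int(y[mask].sum()), int(mask.sum()))
    return out
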