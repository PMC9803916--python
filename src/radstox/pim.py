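"""Probabilistic index models (PIM) for comparing score distributions.

The probabilistic index of two patients with covariates X_i, X_j is

    PI(X_i, X_j) = P(Y_i < Y_j) + 1/2 P(Y_i = Y_j),

the probability that a patient randomly drawn from one profile has the
worse (greater) score than one drawn from the other, with ties split
evenly. The model places a link function over a linear predictor in the
covariate difference,

    g(PI) = (X_j - X_i)' beta,

and estimates beta from all ordered pairs of distinct patients via the
estimating equation

    U(beta) = sum_pairs Z_ij * dm/deta / v_ij * (r_ij - m_ij) = 0,

where Z_ij = X_j - X_i, r_ij = I(Y_i < Y_j) + 1/2 I(Y_i = Y_j), m_ij is
the inverse link of Z_ij' beta and v_ij = m_ij (1 - m_ij) is the working
variance. Under the logit link dm/deta = v and the equation reduces to the
logistic-score form sum Z (r - m) = 0, solved by damped Newton iteration.

Because pseudo-observations sharing a patient are dependent, the variance
is the sandwich A^-1 B A^-1 with A the estimating-equation Jacobian and B
accumulating cross-products of pair-level scores over every two pairs that
share at least one patient (subject-level clustering); disjoint pairs
contribute only their own outer product.

For an unadjusted two-group model the root of the estimating equation is
the empirical placement probability (number of cross-group wins plus half
the ties over all cross pairs) mapped through the link — a useful exact
oracle, checked in the test suite by brute-force pair counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy import stats

from .exceptions import ConvergenceError, RankDeficiencyError, SeparationError

Z_95 = 1.96  # normal quantile used throughout for Wald 95% intervals

#: Linear predictors beyond this magnitude put the fitted PI within ~3e-7
#: of 0 or 1; a fit driven there is treated as separated, not converged.
ETA_SEPARATION = 15.0


@dataclass(frozen=True)
class PseudoObservations:
    """Pairwise pseudo-observations underlying a PIM fit.

    ``i_index``/``j_index`` hold positions into ``ids``; ``reverse`` maps a
    pair's row to the row of its reversed orientation (or -1 when the pair
    policy did not admit the reverse).
    """

    ids: Tuple[str, ...]
    i_index: np.ndarray
    j_index: np.ndarray
    response: np.ndarray
    Z: np.ndarray
    exog_names: Tuple[str, ...]
    reverse: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.response.shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    def reversed(self) -> "PseudoObservations":
        """Same pairs with every orientation flipped (for antisymmetry checks)."""
        order = np.arange(self.n_pairs)
        return PseudoObservations(
            ids=self.ids,
            i_index=self.j_index.copy(),
            j_index=self.i_index.copy(),
            response=1.0 - self.response,
            Z=-self.Z,
            exog_names=self.exog_names,
            reverse=self.reverse[order],
        )


def build_pseudo_observations(
    scores: Sequence[float],
    design,
    ids: Optional[Sequence[str]] = None,
    pair_policy: str = "all",
) -> PseudoObservations:
    """Expand per-patient scores and covariates into ordered-pair form.

    ``design`` is a DataFrame or 2-D array of per-patient covariates
    (without intercept: only covariate differences are identified). The
    default policy admits every ordered pair of distinct patients.
    """
    y = np.asarray(scores, dtype=float)
    n = y.shape[0]
    if n < 2:
        raise ValueError("at least two patients are required to form pairs")
    if isinstance(design, pd.DataFrame):
        names = tuple(str(c) for c in design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = tuple(f"x{k}" for k in range(X.shape[1]))
    if X.shape[0] != n:
        raise ValueError("scores and design must have the same number of patients")
    if ids is None:
        ids = tuple(str(k) for k in range(n))
    else:
        ids = tuple(str(v) for v in ids)

    if pair_policy != "all":
        raise ValueError(f"unknown pair_policy {pair_policy!r}")
    iu, ju = np.triu_indices(n, k=1)
    m = iu.shape[0]
    i_index = np.concatenate([iu, ju])
    j_index = np.concatenate([ju, iu])
    reverse = np.concatenate([np.arange(m) + m, np.arange(m)])

    yi = y[i_index]
    yj = y[j_index]
    response = (yi < yj).astype(float) + 0.5 * (yi == yj)
    Z = X[j_index] - X[i_index]
    return PseudoObservations(
        ids=ids,
        i_index=i_index,
        j_index=j_index,
        response=response,
        Z=Z,
        exog_names=names,
        reverse=reverse,
    )


@dataclass(frozen=True)
class PiContrast:
    """A probabilistic-index estimate for one linear contrast of beta."""

    contrast: np.ndarray
    pi: float
    ci_lower: float
    ci_upper: float
    p_value: float
    estimate_linear: float
    se_linear: float


class ProbabilisticIndexModel:
    """statsmodels-style model object; ``fit()`` returns :class:`PIMResults`."""

    def __init__(self, pseudo: PseudoObservations, link: str = "logit"):
        if link != "logit":
            raise ValueError(f"unsupported link {link!r}; only 'logit' is implemented")
        self.pseudo = pseudo
        self.link = link
        self._check_rank()

    @classmethod
    def from_scores(
        cls,
        scores: Sequence[float],
        design,
        ids: Optional[Sequence[str]] = None,
        link: str = "logit",
    ) -> "ProbabilisticIndexModel":
        return cls(build_pseudo_observations(scores, design, ids=ids), link=link)

    @classmethod
    def from_groups(
        cls,
        scores_ref: Sequence[float],
        scores_trt: Sequence[float],
        link: str = "logit",
    ) -> "ProbabilisticIndexModel":
        """Unadjusted two-group model: a single treatment indicator."""
        y = np.concatenate([np.asarray(scores_ref, float), np.asarray(scores_trt, float)])
        x = np.concatenate(
            [np.zeros(len(scores_ref)), np.ones(len(scores_trt))]
        )[:, None]
        pseudo = build_pseudo_observations(y, x)
        pseudo = PseudoObservations(
            ids=pseudo.ids,
            i_index=pseudo.i_index,
            j_index=pseudo.j_index,
            response=pseudo.response,
            Z=pseudo.Z,
            exog_names=("group",),
            reverse=pseudo.reverse,
        )
        return cls(pseudo, link=link)

    def _check_rank(self):
        Z = self.pseudo.Z
        if Z.shape[1] == 0:
            raise ValueError("design has no columns")
        # QR on the pair-level design; tiny diagonal entries flag collinearity
        _, r = np.linalg.qr(Z)
        diag = np.abs(np.diag(r))
        scale = diag.max() if diag.max() > 0 else 1.0
        bad = [
            self.pseudo.exog_names[k]
            for k in range(Z.shape[1])
            if diag[k] <= 1e-10 * scale
        ]
        if bad:
            raise RankDeficiencyError(bad)

    def score(self, params: np.ndarray) -> np.ndarray:
        Z, r = self.pseudo.Z, self.pseudo.response
        m = expit(Z @ params)
        return Z.T @ (r - m)

    def fit(
        self,
        start: Optional[np.ndarray] = None,
        maxiter: int = 100,
        gtol: float = 1e-8,
        xtol: float = 1e-10,
        max_halvings: int = 20,
    ) -> "PIMResults":
        """Damped Newton solve of the estimating equation.

        Convergence requires both the max-norm of the estimating function
        below ``gtol`` and the last Newton step below ``xtol``. A fit that
        satisfies these only by driving linear predictors to the boundary
        raises :class:`SeparationError`.
        """
        Z, r = self.pseudo.Z, self.pseudo.response
        p = Z.shape[1]
        beta = np.zeros(p) if start is None else np.asarray(start, float).copy()

        def unorm(b):
            return float(np.max(np.abs(self.score(b))))

        converged = False
        for _ in range(maxiter):
            eta = Z @ beta
            m = expit(eta)
            U = Z.T @ (r - m)
            if float(np.max(np.abs(U))) < gtol:
                converged = True
                break
            w = m * (1.0 - m)
            A = Z.T @ (Z * w[:, None])
            try:
                step = np.linalg.solve(A, U)
            except np.linalg.LinAlgError:
                raise SeparationError(
                    "singular estimating-equation Jacobian; the working "
                    "variances have collapsed (complete separation)"
                )
            # step halving: never accept a step that increases |U|
            u0 = float(np.max(np.abs(U)))
            for _h in range(max_halvings + 1):
                candidate = beta + step
                if unorm(candidate) <= u0 or _h == max_halvings:
                    break
                step = step / 2.0
            beta = beta + step
            if float(np.max(np.abs(step))) < xtol and unorm(beta) < gtol:
                converged = True
                break

        eta = Z @ beta
        if float(np.max(np.abs(eta))) > ETA_SEPARATION:
            raise SeparationError(
                "fitted linear predictors diverged to the boundary "
                "(all cross-group comparisons won by one group); report the "
                "boundary probabilistic index descriptively instead"
            )
        if not converged:
            raise ConvergenceError(
                f"PIM Newton iteration did not converge in {maxiter} iterations "
                f"(|U| = {unorm(beta):.3e})"
            )

        cov = self._sandwich(beta)
        return PIMResults(model=self, params=beta, cov_params=cov, converged=True)

    def _sandwich(self, beta: np.ndarray) -> np.ndarray:
        """A^-1 B A^-1 with B summed over pairs sharing a patient.

        With S_k the sum of pair scores over all pairs containing patient k,
        sum_k S_k S_k' counts each (p, q) combination once per shared
        patient: pairs sharing one patient once, and p = q or q = reverse(p)
        (two shared patients) twice. Subtracting one copy of the latter
        leaves exactly one contribution per dependent combination.
        """
        ps = self.pseudo
        Z, r = ps.Z, ps.response
        m = expit(Z @ beta)
        w = m * (1.0 - m)
        A = Z.T @ (Z * w[:, None])
        U = Z * (r - m)[:, None]  # per-pair scores

        n, p = ps.n_subjects, Z.shape[1]
        S = np.zeros((n, p))
        np.add.at(S, ps.i_index, U)
        np.add.at(S, ps.j_index, U)
        B = S.T @ S
        B -= U.T @ U
        has_rev = ps.reverse >= 0
        Urev = U[ps.reverse[has_rev]]
        B -= U[has_rev].T @ Urev

        Ainv = np.linalg.inv(A)
        cov = Ainv @ B @ Ainv
        return (cov + cov.T) / 2.0


class PIMResults:
    """Fitted PIM: coefficients, sandwich covariance, and PI contrasts."""

    def __init__(
        self,
        model: ProbabilisticIndexModel,
        params: np.ndarray,
        cov_params: np.ndarray,
        converged: bool,
    ):
        self.model = model
        self.params = params
        self.cov_params = cov_params
        self.converged = converged
        self.exog_names = model.pseudo.exog_names
        self.n_pairs = model.pseudo.n_pairs
        self.n_subjects = model.pseudo.n_subjects
        self.link = model.link

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def pi_contrast(self, contrast: Sequence[float]) -> PiContrast:
        """PI, Wald 95% CI and p-value for a linear contrast of beta.

        The interval is formed on the linear-predictor scale and mapped
        through the inverse link, so it always stays inside (0, 1). The
        p-value tests PI = 0.5, i.e. contrast' beta = 0.
        """
        if not self.converged:
            raise ConvergenceError("pi_contrast requires a converged fit")
        c = np.asarray(contrast, dtype=float)
        if c.shape != self.params.shape:
            raise ValueError(
                f"contrast length {c.shape} does not match {self.params.shape}"
            )
        est = float(c @ self.params)
        var = float(c @ self.cov_params @ c)
        se = float(np.sqrt(max(var, 0.0)))
        if se == 0.0:
            p = 1.0 if est == 0.0 else 0.0
            lo = hi = est
        else:
            z = est / se
            p = float(2.0 * stats.norm.sf(abs(z)))
            lo, hi = est - Z_95 * se, est + Z_95 * se
        return PiContrast(
            contrast=c,
            pi=float(expit(est)),
            ci_lower=float(expit(lo)),
            ci_upper=float(expit(hi)),
            p_value=p,
            estimate_linear=est,
            se_linear=se,
        )

    def summary(self) -> str:
        lines = [
            "Probabilistic Index Model (logit link)",
            f"subjects: {self.n_subjects}   pseudo-observations: {self.n_pairs}",
            f"{'term':<24}{'coef':>10}{'se':>10}{'PI':>8}{'95% CI':>20}{'p':>10}",
        ]
        for k, name in enumerate(self.exog_names):
            c = np.zeros_like(self.params)
            c[k] = 1.0
            ct = self.pi_contrast(c)
            lines.append(
                f"{name:<24}{self.params[k]:>10.4f}{self.bse[k]:>10.4f}"
                f"{ct.pi:>8.4f}{f'({ct.ci_lower:.4f}, {ct.ci_upper:.4f})':>20}"
                f"{ct.p_value:>10.4g}"
            )
        return "\n".join(lines)


def fit_pim(pseudo: PseudoObservations, link: str = "logit", **kwargs) -> PIMResults:
    """Functional wrapper around :class:`ProbabilisticIndexModel`."""
    return ProbabilisticIndexModel(pseudo, link=link).fit(**kwargs)


def placement_probability(
    scores_ref: Sequence[float], scores_trt: Sequence[float]
) -> float:
    """Empirical P(Y_ref < Y_trt) + 1/2 P(=) by direct pair counting."""
    a = np.asarray(scores_ref, float)[:, None]
    b = np.asarray(scores_trt, float)[None, :]
    return float(np.mean((a < b) + 0.5 * (a == b)))
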