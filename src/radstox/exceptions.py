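"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation problems (schema or
invariant violations) exit 2, numerical failures (separation, divergence,
boundary estimates, rank deficiency) exit 3, and I/O problems exit 4.
"""

from __future__ import annotations

from typing import Sequence


class RadstoxError(Exception):
    """Base class for package errors."""


class SchemaError(RadstoxError):
    """A malformed value in a delimited-text input file.

    Names the file, 1-based line number and field so the offending cell can
    be located directly.
    """

    def __init__(self, file: str, line: int, field: str, message: str):
        self.file = str(file)
        self.line = line
        self.field = field
        super().__init__(f"{self.file}:{line}: field '{field}': {message}")


class CohortValidationError(RadstoxError):
    """A cohort-level invariant violation, listing the offending patients."""

    def __init__(self, message: str, patient_ids: Sequence[str] = ()):
        self.patient_ids = tuple(patient_ids)
        if self.patient_ids:
            message = f"{message} (patients: {', '.join(self.patient_ids)})"
        super().__init__(message)


class NumericalError(RadstoxError):
    """Base class for estimation failures."""


class SeparationError(NumericalError):
    """Complete separation: the estimating equation has no finite root.

    For a two-group probabilistic index model this means every cross-group
    comparison is won by the same group; report the boundary PI (0 or 1)
    descriptively instead of a model fit.
    """


class ConvergenceError(NumericalError):
    """Iteration limit reached without meeting the convergence criteria."""


class RankDeficiencyError(NumericalError):
    """Collinear design columns, named so the caller can drop one."""

    def __init__(self, columns: Sequence[str]):
        self.columns = tuple(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class BoundaryError(NumericalError):
    """A fitted rate sits on the boundary of the parameter space.

    Raised when a group has zero events under a log link, where the
    maximum-likelihood log-mean diverges to -inf; the relative risk is 0 or
    infinite and should be reported as such, not as a spuriously large
    finite number.
    """

    def __init__(self, message: str, terms: Sequence[str] = ()):
        self.terms = tuple(terms)
        super().__init__(message)
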