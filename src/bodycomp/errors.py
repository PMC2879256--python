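"""Exception hierarchy shared by all bodycomp modules."""


class BodycompError(Exception):
    """Base class for all bodycomp errors."""


class ValidationError(BodycompError, ValueError):
    """An input violates a documented invariant; the message names the field."""


class ConfigurationError(BodycompError, ValueError):
    """Unknown registry variant or malformed configuration."""


class DomainError(BodycompError, ValueError):
    """A value lies outside a model's mathematical domain (e.g. ln of FM <= 0)."""


class InfeasibleMassError(BodycompError, ValueError):
    """Total body mass admits no non-negative-fat solution.

    Attributes
    ----------
    zero_fat_ffm_kg : float
        The model's fat-free mass at FM = 0, the lower bound on feasible
        total body mass for the given covariates.
    """

    def __init__(self, message: str, zero_fat_ffm_kg: float):
        super().__init__(message)
        self.zero_fat_ffm_kg = zero_fat_ffm_kg


class AmbiguousRootError(BodycompError, RuntimeError):
    """The total-mass function is non-monotone; every bracketed root is listed.

    Attributes
    ----------
    roots : list[float]
        All roots located on the search interval.
    """

    def __init__(self, message: str, roots: list):
        super().__init__(message)
        self.roots = list(roots)


class FitError(BodycompError, RuntimeError):
    """Regression failure, e.g. a rank-deficient design matrix."""


class ModelValidityError(BodycompError, ValueError):
    """The energy-balance reduction is invalid at the requested state."""


class CohortCsvError(BodycompError, ValueError):
    """One or more cohort CSV rows failed validation.

    Attributes
    ----------
    row_errors : list[tuple[int, str, str]]
        (line number, record id, message) per offending row.
    """

    def __init__(self, message: str, row_errors: list):
        super().__init__(message)
        self.row_errors = list(row_errors)
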