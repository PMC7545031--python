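"""Exception hierarchy shared across the package."""


class RhizofitError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RhizofitError, ValueError):
    """A model parameter record violates its constraints."""


class ValidationError(RhizofitError, ValueError):
    """Input data fail a structural or domain check."""


class DomainError(RhizofitError, ValueError):
    """Evaluation requested outside a function's valid domain."""


class SingularDesignError(RhizofitError, ValueError):
    """A regression design matrix is rank deficient (e.g. constant predictor)."""


class FitFailure(RhizofitError, RuntimeError):
    """Nonlinear least squares did not converge.

    Carries the best iterate and solver diagnostics so callers (e.g. model
    selection, bootstrap) can inspect or discard the attempt.
    """

    def __init__(self, message, *, best_theta=None, diagnostics=None):
        super().__init__(message)
        self.best_theta = best_theta
        self.diagnostics = diagnostics or {}


class AllFitsFailedError(FitFailure):
    """Every candidate model (or every bootstrap replicate) failed to fit."""

    def __init__(self, message, *, failures=None):
        super().__init__(message)
        self.failures = failures or {}
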