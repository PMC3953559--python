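"""Exception hierarchy shared across the package."""


class HDBayesError(Exception):
    """Base class for package errors."""


class ValidationError(HDBayesError, ValueError):
    """Invalid input data or configuration."""


class DomainError(ValidationError):
    """Model evaluated outside its mathematical domain."""


class ParameterArityError(ValidationError):
    """Parameter vector length does not match the model form."""


class FormatError(ValidationError):
    """Malformed input file (missing columns, unknown format)."""


class ConvergenceError(HDBayesError):
    """Optimizer failed to converge; carries the best iterate found."""

    def __init__(self, message, best_params=None, best_sse=None):
        super().__init__(message)
        self.best_params = best_params
        self.best_sse = best_sse


class DegeneratePriorError(ValidationError):
    """Posterior chain has zero variance; cannot moment-match a prior."""


class MixingWarning(UserWarning):
    """MCMC acceptance or convergence diagnostics look poor."""


class SingularityWarning(UserWarning):
    """Rank-deficient Jacobian at the least-squares solution."""
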