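"""Exception hierarchy for the cafcd pipeline."""


class CafcdError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(CafcdError, ValueError):
    """An argument violates an operation's preconditions."""


class ConfigurationError(CafcdError, ValueError):
    """A configuration object is inconsistent or rejected."""


class ConstructiveFailureError(CafcdError, RuntimeError):
    """A randomized construction could not be realized within its retry budget."""

    def __init__(self, message: str, retries: int):
        super().__init__(f"{message} (retry limit: {retries})")
        self.retries = retries


class EmptyInputError(CafcdError, ValueError):
    """An operation requiring nonempty input received an empty collection."""


class FitFailureError(CafcdError, RuntimeError):
    """A model fit failed to converge; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InsufficientSupportError(CafcdError, ValueError):
    """Too few distinct support points for the requested fit."""


class ICAConvergenceError(CafcdError, RuntimeError):
    """ICA failed to converge within the retry budget; the network should be
    excluded from meta-state statistics rather than imputed."""

    def __init__(self, message: str, retries: int):
        super().__init__(message)
        self.retries = retries


class DegenerateBasisError(CafcdError, ValueError):
    """A pattern basis is rank-deficient and cannot support regression."""


class DegenerateComponentError(CafcdError, ValueError):
    """A weight component is identically zero and cannot be discretized."""
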