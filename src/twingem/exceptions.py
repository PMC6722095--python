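"""Exception hierarchy used across the package."""


class TwingemError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TwingemError, ValueError):
    """Invalid simulation or model configuration."""


class DataValidationError(TwingemError, ValueError):
    """Input data violate the documented schema or invariants."""


class LikelihoodError(TwingemError, ValueError):
    """Likelihood cannot be evaluated (e.g. non-positive-definite moments)."""


class FitError(TwingemError, RuntimeError):
    """Estimation failed (non-convergence, degenerate data)."""


class NotNestedError(TwingemError, ValueError):
    """Likelihood-ratio test requested for models that are not nested."""
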