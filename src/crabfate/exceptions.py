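"""Exception hierarchy shared across the package."""


class CrabfateError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CrabfateError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(CrabfateError, ValueError):
    """Input data violates a structural rule (schema, status transition, ids)."""


class UndefinedValueError(CrabfateError, ValueError):
    """A statistic is undefined for the given input (e.g. empty denominator)."""


class DataInconsistencyError(CrabfateError, ValueError):
    """Counts contradict the dwelling accounting identity."""


class DegenerateFitError(CrabfateError, RuntimeError):
    """A model fit is degenerate (e.g. no continuous observations for a beta fit)."""
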