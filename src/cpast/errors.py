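"""Exception types shared across the package."""


class CpastError(Exception):
    """Base class for package errors."""


class ConfigurationError(CpastError, ValueError):
    """Invalid configuration value or a stimulus layout that does not fit the grid."""


class DegenerateInputError(CpastError, ValueError):
    """Numerically degenerate input (all-zero column, empty candidate set, ...)."""


class UndefinedMetricError(CpastError, ValueError):
    """A summary statistic is undefined for the given inputs (zero denominator)."""
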