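"""Exception hierarchy shared across the package."""


class KdiffError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(KdiffError, ValueError):
    """An argument or configuration value violates its contract."""


class ConfigError(ParameterError):
    """A configuration file is malformed (unknown key, bad value)."""


class EstimationError(KdiffError):
    """A K/D estimate cannot be formed (e.g. fewer than two points of a type)."""


class UndefinedEstimateError(EstimationError):
    """An estimate exists but is undefined at one or more ranges
    (no border-eligible centers); carries the offending range indices."""

    def __init__(self, message: str, range_indices=None):
        super().__init__(message)
        self.range_indices = range_indices


class DegenerateNullError(EstimationError):
    """The permutation null distribution is degenerate (zero variance at a range)."""
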