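"""Exception hierarchy for the hypnoseeg pipeline.

Three broad failure classes are distinguished so the CLI can map them to
distinct exit codes: configuration problems, data/validation problems, and
numerical failures at run time.
"""


class HypnosEEGError(Exception):
    """Base class for all package errors."""


class ConfigError(HypnosEEGError):
    """Invalid configuration value or unknown option."""


class ValidationError(HypnosEEGError):
    """Input data violates a documented precondition."""


class StateError(HypnosEEGError):
    """Operation applied in an invalid order (e.g. re-referencing twice)."""


class NumericalError(HypnosEEGError):
    """Numerical failure (NaN loss, rank-deficient covariance, ...)."""
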