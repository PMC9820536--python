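"""Exception hierarchy shared by all modules."""


class EmgaitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EmgaitError):
    """A file or metadata record does not conform to the expected schema."""


class DataError(EmgaitError):
    """Input data values are invalid (non-finite samples, non-uniform time base)."""


class ParameterError(EmgaitError, ValueError):
    """An analysis parameter violates its precondition."""


class UsageError(EmgaitError):
    """API misuse: mismatched channels, unknown result type, missing channel."""


class InsufficientDataError(EmgaitError):
    """Too few observations to compute the requested statistic."""


class ConfigError(EmgaitError):
    """A generative configuration is internally inconsistent."""
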