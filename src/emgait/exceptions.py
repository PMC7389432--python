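"""Exception hierarchy shared across the package."""


class EmgaitError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EmgaitError, ValueError):
    """Invalid parameter value (non-positive duration, bad fraction, ...)."""


class SignalLengthError(EmgaitError, ValueError):
    """Signal too short for the requested operation."""


class DegenerateSignalError(EmgaitError, ValueError):
    """Constant channel: min–max normalization is undefined."""


class DegenerateTrainingError(EmgaitError, ValueError):
    """Training set contains a single class; nothing to learn."""


class UndefinedMetricError(EmgaitError, ValueError):
    """Metric has an empty denominator (e.g., no unmasked windows)."""


class DataFormatError(EmgaitError, ValueError):
    """Malformed subject/events file."""
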