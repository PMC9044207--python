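"""Exception hierarchy shared across the pipeline stages."""


class PulsekitError(Exception):
    """Base class for all pulsekit errors."""


class ParameterError(PulsekitError, ValueError):
    """A parameter violates its documented domain."""


class ExtractionError(PulsekitError):
    """Skin/patch extraction could not produce any usable trace."""


class OverlapViolationError(ParameterError):
    """Window stride must be strictly smaller than the window length."""


class WindowTooLongError(ParameterError):
    """Requested analysis window exceeds the signal duration."""


class SignalLengthError(ParameterError):
    """Signal too short for the requested operation."""


class RegistryError(PulsekitError, KeyError):
    """Unknown pulse-extraction method name."""


class AggregationError(PulsekitError):
    """No valid per-patch estimate available in a window."""


class ConfigError(PulsekitError):
    """Malformed or inconsistent experiment configuration."""


class ResultsFormatError(PulsekitError):
    """Persisted results file has an unexpected schema or version."""


class StatsError(PulsekitError):
    """Statistical comparison could not be carried out."""
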