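"""Exception types shared across the package."""


class EcgWavesError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(EcgWavesError, ValueError):
    """A configuration field is unknown or out of its valid range."""


class InsufficientBeatsError(EcgWavesError, ValueError):
    """Heart rate and duration admit fewer than two beats; R-R statistics
    are undefined."""


class UndefinedMetricError(EcgWavesError, ZeroDivisionError):
    """A metric's denominator is zero (or a feature has no eligible events)."""


class UncalibratableImageError(EcgWavesError, ValueError):
    """The image contains no detectable calibration grid."""
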