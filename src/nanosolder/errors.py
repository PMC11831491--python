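"""Exception hierarchy shared across the package."""


class NanosolderError(Exception):
    """Base class for all package-specific errors."""


class SpectrumCoverageError(NanosolderError, ValueError):
    """Spectrum does not cover the wavelength range an operation needs."""


class UndefinedRatioError(NanosolderError, ArithmeticError):
    """Band ratio undefined (denominator band integrates to zero or less)."""


class InversionError(NanosolderError, ArithmeticError):
    """FIR -> temperature inversion is singular (fir <= 0 or ln(fir) = a)."""


class ExtrapolationError(NanosolderError, ValueError):
    """Requested temperature lies outside the emission database range."""


class ConfigurationError(NanosolderError, ValueError):
    """Inconsistent or malformed configuration."""


class ParameterError(NanosolderError, ValueError):
    """Invalid physical parameter value."""


class GeometryError(NanosolderError, ValueError):
    """Invalid optical geometry (e.g. fiber standoff <= 0)."""


class NotFittedError(NanosolderError, RuntimeError):
    """Operation requires a trained/fitted model."""


class SchemaError(NanosolderError, ValueError):
    """Archive schema version mismatch or corrupted file."""


class CalibrationRangeWarning(UserWarning):
    """Temperature inverted outside the calibration's validated range."""
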