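"""Exception types shared across the model hierarchy."""


class HiersongError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(HiersongError, ValueError):
    """A parameter violates its documented constraints."""


class InvalidSizeError(HiersongError, ValueError):
    """A matrix/vector has an inadmissible shape."""


class DivergenceError(HiersongError, RuntimeError):
    """Numerical integration left the configured bounds.

    Carries the model time at which the divergence was detected.
    """

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class AlignmentError(HiersongError, ValueError):
    """Two time series do not share a compatible time grid."""


class ConfigurationError(HiersongError, ValueError):
    """Inconsistent model configuration."""


class InvalidControlError(HiersongError, ValueError):
    """A vocal control signal is unphysical (e.g. non-positive stiffness)."""


class CalibrationError(HiersongError, RuntimeError):
    """Rate-constant calibration failed to bracket the target."""
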