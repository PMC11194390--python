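"""Exception hierarchy shared across the package."""


class PulsekfdError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PulsekfdError, ValueError):
    """A function argument or configuration value is invalid."""


class DataError(PulsekfdError, ValueError):
    """Input data violate a contract (non-finite, degenerate, malformed)."""


class ConvergenceError(PulsekfdError, RuntimeError):
    """Periodic steady state not reached within the warm-up budget.

    Carries the last cycle-to-cycle residual in ``residual`` (mmHg).
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DetectionError(PulsekfdError, RuntimeError):
    """Beat segmentation or fiducial-point detection failed."""


class FitError(PulsekfdError, RuntimeError):
    """A model fit (Gaussian decomposition, regression) failed."""


class FormatError(PulsekfdError, ValueError):
    """A file does not conform to the expected on-disk format."""


class ScalingError(PulsekfdError, ValueError):
    """KFD scaling produced a degenerate diameter (log denominator <= 0)."""
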