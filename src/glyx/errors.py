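"""Exception hierarchy shared across the package."""


class GlyxError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(GlyxError, ValueError):
    """A physical or geometric parameter is out of its admissible range."""


class SolverError(GlyxError, RuntimeError):
    """A boundary-value solve failed to converge.

    Carries the residual norm of the failed solve in ``residual_norm``.
    """

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm


class UnderDeterminedError(GlyxError, ValueError):
    """Fewer measurement points than free parameters in a fit."""


class NoMembraneDetectedError(GlyxError, ValueError):
    """Membrane channel carries no usable axial focus peak."""


class NoSignalError(GlyxError, ValueError):
    """No probe signal above background along the z-axis."""


class UndefinedFractionError(GlyxError, ValueError):
    """Quadrant fractions are undefined (zero total probe signal)."""


class FormatError(GlyxError, ValueError):
    """An input file does not match the expected layout."""


class ConfigError(GlyxError, ValueError):
    """A run configuration failed validation."""
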