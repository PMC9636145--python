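"""Exception hierarchy shared across the package."""


class PVRetinaError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(PVRetinaError, ValueError):
    """Invalid or inconsistent implant geometry."""


class TimingError(PVRetinaError, ValueError):
    """Inconsistent pulse/reversal timing in an illumination protocol."""


class DomainError(PVRetinaError, ValueError):
    """Input outside the physical domain of an operation."""


class SolverError(PVRetinaError, RuntimeError):
    """A nonlinear or linear solve failed to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class StiffnessError(SolverError):
    """Adaptive time stepping underflowed the minimum step size."""


class NonStationaryError(SolverError):
    """Periodic steady state was not reached within the allowed number of periods."""


class EstimationError(PVRetinaError, RuntimeError):
    """The acuity estimator cannot produce an estimate from the given data."""


class ConfigError(PVRetinaError, ValueError):
    """Invalid experiment configuration."""
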