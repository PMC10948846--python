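"""Exception types raised across the package."""


class CranioflowError(Exception):
    """Base class for package errors."""


class InvalidGeometryError(CranioflowError, ValueError):
    """Geometry parameters are inconsistent (e.g. ventricle outside brain)."""


class InvalidMeshError(CranioflowError, ValueError):
    """Mesh lacks required labels or contains degenerate cells."""


class MeshingError(CranioflowError, RuntimeError):
    """Mesh generation failed; message echoes the offending geometry."""


class SolverDivergenceError(CranioflowError, RuntimeError):
    """Nonlinear or coupling iteration diverged; carries residual history."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = list(residuals) if residuals is not None else []


class NotConvergedError(CranioflowError, RuntimeError):
    """A result flagged non-converged was used where convergence is required."""
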