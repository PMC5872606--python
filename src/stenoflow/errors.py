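"""Exception types raised across the package."""


class StenoflowError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(StenoflowError, ValueError):
    """Geometric parameters are inconsistent (e.g. throat wider than vessel)."""


class OutOfDomainError(StenoflowError, ValueError):
    """A coordinate falls outside the meshed/defined domain."""


class ConfigurationError(StenoflowError, ValueError):
    """Invalid solver, grid or case configuration."""


class ConvergenceError(StenoflowError, RuntimeError):
    """Iterative solve failed to reach the requested tolerances.

    Carries the residual history accumulated up to the failure so the
    caller can inspect the stall/divergence pattern.
    """

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history


class NumericalBreakdownError(ConvergenceError):
    """A non-finite value appeared in a field during iteration."""


class OracleError(StenoflowError, RuntimeError):
    """Semi-analytic reference solution could not be bracketed/converged."""


class StaleFieldError(StenoflowError, ValueError):
    """A post-processing routine was handed an unconverged flow field."""
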