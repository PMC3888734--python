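"""Exception hierarchy shared across the package."""


class FoldCausticError(Exception):
    """Base class for all package errors."""


class ValidationError(FoldCausticError, ValueError):
    """Invalid user input: bad configuration, bad parameter, shape mismatch."""


class IntegrationBlowupError(FoldCausticError, RuntimeError):
    """The integrator produced a non-finite state.

    Attributes
    ----------
    t_reached : float
        Last time at which the state was still finite.
    """

    def __init__(self, message: str, t_reached: float | None = None):
        super().__init__(message)
        self.t_reached = t_reached


class FamilyIntegrationError(FoldCausticError, RuntimeError):
    """A member of a trajectory family failed to integrate.

    Attributes
    ----------
    u : float
        Family parameter of the failing member.
    """

    def __init__(self, message: str, u: float):
        super().__init__(message)
        self.u = u


class NonStationaryTrajectoryError(FoldCausticError, ValueError):
    """A second-variation routine was handed a non-stationary trajectory.

    Attributes
    ----------
    residual : float
        The Euler-Lagrange residual that exceeded the threshold.
    """

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class IntegrabilityError(FoldCausticError, ValueError):
    """A Boltzmann-weight integral does not converge (non-confining potential)."""


class OptimizationError(FoldCausticError, RuntimeError):
    """An optimizer failed to converge; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
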