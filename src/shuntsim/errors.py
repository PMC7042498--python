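"""Typed exceptions raised across the shuntsim package."""


class ShuntSimError(Exception):
    """Base class for all shuntsim errors."""


class InvalidCaseError(ShuntSimError, ValueError):
    """A case definition violates its invariants (e.g. alpha outside [0, 1))."""


class InvalidSpecError(ShuntSimError, ValueError):
    """A component specification violates its invariants (e.g. d <= 0)."""


class InvalidArgumentError(ShuntSimError, ValueError):
    """An operation received an argument outside its stated precondition."""


class SolverError(ShuntSimError, RuntimeError):
    """The steady-state solver failed to converge.

    Carries the last flow residual (m^3/s) in :attr:`residual`.
    """

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class ReversedShuntError(ShuntSimError, RuntimeError):
    """The converged solution carries pulmonary-to-aortic shunt flow."""


class PhysiologicInfeasibleError(ShuntSimError, ValueError):
    """An oxygen-balance quantity left its physiologic range (content <= 0,
    DO2 <= 0).  Raised instead of clamping so sweeps can mark the case."""


class IncompleteSolutionError(ShuntSimError, ValueError):
    """A metric was requested on a solution missing required port states."""


class UndefinedRatioError(ShuntSimError, ZeroDivisionError):
    """A flow-split ratio is undefined (zero denominator flow)."""


class ConfigError(ShuntSimError, ValueError):
    """A generator or I/O configuration is degenerate or inconsistent."""
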