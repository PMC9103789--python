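"""Exception hierarchy for szddi.

All package errors derive from :class:`SzddiError` so callers can catch one
base class; the CLI maps any of these to a nonzero exit with a one-line
machine-parsable reason.
"""


class SzddiError(Exception):
    """Base class for all szddi errors."""


class AssayParseError(SzddiError):
    """A CSV cell could not be parsed; message names the row and column."""


class AssayValidationError(SzddiError):
    """A dataset violates an assay-design invariant; message names it."""


class FitError(SzddiError):
    """A nonlinear fit failed to converge.

    May carry ``residuals`` and/or ``fallback`` diagnostics set by the fitter.
    """

    def __init__(self, message, residuals=None, fallback=None):
        super().__init__(message)
        self.residuals = residuals
        self.fallback = fallback


class NoInhibitionError(FitError):
    """Responses are flat: no concentration-dependent inhibition detected."""


class DomainError(SzddiError):
    """An argument is outside the mathematical domain of an operation."""


class ConfigurationError(SzddiError):
    """An interaction/mode/config combination is inconsistent."""


class CalibrationError(SzddiError):
    """Baseline calibration has no solution in bounds.

    ``achievable`` may hold the (low, high) AUC range that was reachable.
    """

    def __init__(self, message, achievable=None):
        super().__init__(message)
        self.achievable = achievable


class SimulationError(SzddiError):
    """The ODE solver failed; ``last_state`` holds the last accepted state."""

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state
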