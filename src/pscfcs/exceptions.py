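"""Exception hierarchy shared across the toolkit.

All toolkit errors derive from :class:`PscfcsError` so callers can catch
one base class; the CLI maps subclasses onto exit codes (invalid input vs.
fit failure).
"""


class PscfcsError(Exception):
    """Base class for all toolkit errors."""


class InvalidArgumentError(PscfcsError, ValueError):
    """An argument violates a precondition (wrong sign, overlap, bad kind)."""


class DegenerateInputError(PscfcsError, ValueError):
    """Input is structurally valid but carries no usable information
    (zero-mean trace, no background bins, empty selection)."""


class UndefinedEfficiencyError(DegenerateInputError):
    """FRET efficiency requested for a burst with zero total photons."""


class InsufficientDataError(PscfcsError, ValueError):
    """Too few points to determine the requested parameters."""


class FitFailureError(PscfcsError, RuntimeError):
    """A nonlinear fit failed to converge or produced an inadmissible
    parameter. Carries the best iterate when available."""

    def __init__(self, message, best_values=None, residual_norm=None):
        super().__init__(message)
        self.best_values = best_values
        self.residual_norm = residual_norm


class UnboundedEstimateError(FitFailureError):
    """The data do not constrain the parameter (e.g. a flat titration):
    the estimate diverges rather than converging to a finite value."""
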