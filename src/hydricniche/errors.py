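"""Exception hierarchy shared across the package.

Every error raised by the analysis layers derives from
:class:`HydricNicheError`, so callers (and the CLI) can catch one base
class. Errors carry enough context to locate the offending stage or input.
"""


class HydricNicheError(Exception):
    """Base class for all package errors."""


class InvalidInputError(HydricNicheError, ValueError):
    """An argument violates a documented precondition."""


class NonCompletionError(HydricNicheError):
    """A temperature regime cannot accumulate 100% development."""


class FitNonConvergenceError(HydricNicheError):
    """Nonlinear least squares failed to converge.

    Attributes
    ----------
    final_cost : float
        Objective value (0.5 * sum of squared residuals) at the last iterate.
    grad_norm : float
        Infinity norm of the gradient at the last iterate.
    """

    def __init__(self, message, final_cost=None, grad_norm=None):
        super().__init__(message)
        self.final_cost = final_cost
        self.grad_norm = grad_norm


class NoRootError(HydricNicheError):
    """The CT_max criterion was not met below the scan ceiling."""


class NoCrossingError(HydricNicheError):
    """Flux means do not change sign across water-potential treatments."""


class EmptyInputError(HydricNicheError, ValueError):
    """No usable records remain after filtering."""


class IncompleteSeriesError(HydricNicheError):
    """A mass series does not span the requested hydration window."""


class OutOfRangeError(HydricNicheError, ValueError):
    """A value lies outside the domain of a retention curve."""


class EmptyWindowError(HydricNicheError):
    """A sensor series does not overlap the requested year window."""


class InsufficientDataError(HydricNicheError):
    """Too few observations for the requested statistic."""


class JoinError(HydricNicheError):
    """Site identifiers could not be paired across tables."""

    def __init__(self, message, unmatched=()):
        super().__init__(message)
        self.unmatched = tuple(unmatched)


class MissingYearError(HydricNicheError, KeyError):
    """A requested year is absent from an annual series."""
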