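"""Exception types shared across the package."""


class ModeHopError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ModeHopError, ValueError):
    """An argument violates a documented precondition."""


class InvalidStateError(ModeHopError, ValueError):
    """A model state violates its invariants (negative counts, Nn > Ntot, ...)."""


class IntegrationDivergedError(ModeHopError, ArithmeticError):
    """The integrator produced a non-finite state.

    Carries the time at which the failure was first observed.
    """

    def __init__(self, t: float, message: str | None = None):
        self.t = t
        super().__init__(message or f"integration diverged (non-finite state) at t = {t:g} min")


class SchemaError(ModeHopError, ValueError):
    """A table file does not have the expected columns."""


class InsufficientDataError(ModeHopError, ValueError):
    """Too few peaks/intervals for the requested analysis."""
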