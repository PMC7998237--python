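"""Exception hierarchy for the gamete-game model family."""


class AnisogameError(Exception):
    """Base class for all package errors."""


class DomainError(AnisogameError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class UnsupportedVariantError(AnisogameError, ValueError):
    """The requested combination of survival functional forms is not supported."""


class ConvergenceError(AnisogameError, RuntimeError):
    """A numerical routine failed to converge; carries the best residual seen."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class PreconditionError(AnisogameError, ValueError):
    """A stated precondition (e.g. "point is an equilibrium") is violated."""


class NoSignChangeError(AnisogameError, ValueError):
    """A bisection criterion does not change truth value across the bracket."""


class ModelContractError(AnisogameError, ValueError):
    """A pluggable fertilization-count model violated its contract."""


class IntegrationError(AnisogameError, RuntimeError):
    """Gradient-dynamics integration hit an invalid state; carries the last valid state."""

    def __init__(self, message: str, last_state=None, last_time: float | None = None):
        super().__init__(message)
        self.last_state = last_state
        self.last_time = last_time
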