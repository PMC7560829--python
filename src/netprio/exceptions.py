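"""Exception hierarchy shared across the package."""


class NetprioError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NetprioError):
    """An input violates a documented precondition or invariant."""


class ParseError(NetprioError):
    """A file could not be parsed; the message names the offending line."""


class ConvergenceError(NetprioError):
    """An iterative solver failed to reach tolerance within its budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class GenerationError(NetprioError):
    """A synthetic-data request is infeasible for the given network."""
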