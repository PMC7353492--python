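"""Exception hierarchy shared by all frostkin modules."""


class FrostkinError(Exception):
    """Base class for all package errors."""


class InvalidInputError(FrostkinError, ValueError):
    """An argument violates a documented precondition."""


class ConvergenceError(FrostkinError, RuntimeError):
    """A nonlinear fit failed to converge; carries the optimizer trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class RankDeficiencyError(FrostkinError, RuntimeError):
    """The regression design cannot identify all parameters."""


class RegionMismatchError(FrostkinError, RuntimeError):
    """A joint confidence region rejects almost every sampled parameter pair."""
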