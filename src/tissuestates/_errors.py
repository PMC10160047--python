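"""Exception types shared across the package."""


class TissueStatesError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(TissueStatesError, ValueError):
    """An argument violates an operation's precondition."""


class EmptySelectionError(TissueStatesError):
    """No chromosome passed the correlation threshold.

    Callers should fall back to a lower threshold or to reference-based
    orientation when this is raised.
    """


class UndefinedStatisticError(TissueStatesError):
    """A statistic is undefined for the given input (e.g. constant field)."""


class ConvergenceError(TissueStatesError):
    """An iterative fit failed to converge within the iteration budget."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
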