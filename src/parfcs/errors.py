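"""Exception hierarchy shared by all analysis modules."""


class ParFCSError(Exception):
    """Base class for all parfcs errors."""


class InvalidParameterError(ParFCSError, ValueError):
    """A physical parameter is outside its valid domain (e.g. tau_d <= 0)."""


class InvalidShapeError(ParFCSError, ValueError):
    """Aspect ratio outside the prolate domain (H < 1), or no prolate solution."""


class InsufficientDataError(ParFCSError, ValueError):
    """Too few data points to attempt the requested fit."""


class InsufficientSignalError(ParFCSError, ValueError):
    """Correlation amplitude indistinguishable from zero: nothing to fit."""


class DegenerateInputError(ParFCSError, ValueError):
    """Input carries no information (e.g. an all-zero histogram)."""


class FitFailureError(ParFCSError, RuntimeError):
    """Optimiser failed to converge; carries the last iterate for inspection."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class TruncationError(ParFCSError, ValueError):
    """Probability mass beyond max_count exceeds tolerance; widen max_count."""
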