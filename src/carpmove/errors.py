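"""Exception types shared across the package."""


class CarpMoveError(Exception):
    """Base class for all labeled errors raised by carpmove."""


class ValidationError(CarpMoveError):
    """Invalid inputs, preconditions, or configuration."""


class FitError(CarpMoveError):
    """Model fitting failed to converge.

    Carries ``best_params``, the best parameter set found across restarts,
    so a caller can inspect or restart from it.
    """

    def __init__(self, message, best_params=None):
        super().__init__(message)
        self.best_params = best_params
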