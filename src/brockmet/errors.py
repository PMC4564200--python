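"""Exception types shared across the package."""


class BrockmetError(Exception):
    """Base class for all package errors."""


class InvalidInputError(BrockmetError, ValueError):
    """An argument violates a documented precondition."""


class VocabularyError(InvalidInputError):
    """A label is outside its closed vocabulary (season, state, sex, age class)."""


class ConfigError(BrockmetError):
    """A configuration value (unit label, model registry entry, path) is unusable."""


class NoStableSegmentError(BrockmetError):
    """No window of the trace met the stability criteria.

    Carries the best diagnostics found so the caller can decide whether to
    relax the criteria or discard the trace.
    """

    def __init__(self, message, best_window=None):
        super().__init__(message)
        self.best_window = best_window
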