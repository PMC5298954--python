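"""Exception types shared across the package."""


class TimeprefError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(TimeprefError):
    """A simulation or pipeline configuration violates its bounds."""


class InputError(TimeprefError):
    """Invalid input to an operation (bad amounts, missing fields, ...)."""


class AdministrationError(TimeprefError):
    """A test administration failed; carries the partial trial log."""

    def __init__(self, message, trials=None):
        super().__init__(message)
        self.trials = trials if trials is not None else []


class FittingError(TimeprefError):
    """Model fitting failed (perfect separation, singular design, ...)."""


class DegenerateOutcomeError(TimeprefError):
    """A statistic is undefined for this outcome (e.g. constant y)."""
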