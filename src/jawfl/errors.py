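"""Exception types raised by the analysis pipeline."""


class JawflError(Exception):
    """Base class for package errors."""


class ConfigurationError(JawflError):
    """A generator or analysis configuration violates its invariants."""


class MissingChannelError(JawflError):
    """A required recording channel is absent from a trial."""

    def __init__(self, channel: str, available=()):
        self.channel = channel
        self.available = tuple(available)
        super().__init__(
            f"required channel {channel!r} not present; available: {sorted(self.available)}"
        )


class NoInteriorOptimumError(JawflError):
    """The fitted FL polynomial has no interior maximum inside the fit range.

    An edge "optimum" means the length ladder failed to bracket the plateau,
    so the result is refused rather than clamped.
    """


class NoActivationError(JawflError):
    """No EMG burst crossed the onset threshold."""
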