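"""Exception types shared across the pipeline."""


class InvalidArgumentError(ValueError):
    """An argument violates an operation's precondition."""


class MissingChannelsError(InvalidArgumentError):
    """Required electrode labels are absent from a recording."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing required channels: {', '.join(self.missing)}")


class DegenerateSignalError(ValueError):
    """A signal has no usable structure (constant channel, no phase sign changes)."""
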