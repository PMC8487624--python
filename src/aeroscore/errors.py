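"""Exception hierarchy shared across the toolkit."""


class AeroscoreError(Exception):
    """Base class for all toolkit errors."""


class FormatError(AeroscoreError, ValueError):
    """A file could not be parsed as the declared format."""


class ValidationError(AeroscoreError, ValueError):
    """Parsed content violates a domain invariant (bad counts, unknown enum, ...)."""


class UndefinedMetricError(AeroscoreError, ValueError):
    """A diversity or distance value is undefined for the given input (e.g. all-zero)."""


class StageError(AeroscoreError, RuntimeError):
    """A stage of the full protocol failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
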