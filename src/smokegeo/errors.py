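"""Exception types shared across the pipeline."""


class SmokegeoError(Exception):
    """Base class for package errors."""


class ConfigError(SmokegeoError, ValueError):
    """Invalid configuration value; message names the offending field."""


class FormatError(SmokegeoError, ValueError):
    """Malformed input file; message names the missing/bad column."""


class EmptyStreamError(SmokegeoError, ValueError):
    """An event stream with no usable GPS fixes."""


class ValidationError(SmokegeoError, ValueError):
    """Invalid argument to an operation."""


class ParticipantSkipped(SmokegeoError):
    """Raised when a participant cannot be modeled (too few samples or one class)."""

    def __init__(self, participant_id: str, reason: str):
        self.participant_id = participant_id
        self.reason = reason
        super().__init__(f"{participant_id}: {reason}")
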