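"""Exception types shared across the pipeline."""


class LvadSoundError(Exception):
    """Base class for all errors raised by lvadsound."""


class ParameterError(LvadSoundError, ValueError):
    """A parameter violates its documented invariant.

    Carries the name of the offending field so callers (and the CLI) can
    point at the exact input that is wrong.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class AudioFormatError(LvadSoundError, ValueError):
    """Malformed, truncated or otherwise unreadable audio file."""


class DegenerateInputError(LvadSoundError, ValueError):
    """Input is formally valid but degenerate (e.g. an all-zero window)."""


class InsufficientDataError(LvadSoundError, ValueError):
    """Too little data to resolve the requested quantity."""


class UnanalyzableRecordingError(LvadSoundError, RuntimeError):
    """Feature extraction failed for a whole recording.

    A structured failure record: never a silently partial feature vector.
    """

    def __init__(self, recording_id: str, reason: str):
        self.recording_id = recording_id
        self.reason = reason
        super().__init__(f"recording {recording_id!r}: {reason}")


class EmptyCohortError(LvadSoundError, ValueError):
    """A cohort specification requested zero recordings."""


class ConfigError(LvadSoundError, ValueError):
    """Invalid or inconsistent run configuration."""
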