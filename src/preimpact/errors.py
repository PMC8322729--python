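"""Exception hierarchy shared across the package."""


class PreimpactError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PreimpactError):
    """A file does not conform to the expected on-disk dialect."""


class IntegrityError(PreimpactError):
    """Data violates an internal consistency rule (frame order, label order, ...)."""


class UsageError(PreimpactError, ValueError):
    """The caller passed arguments outside an operation's contract."""


class RangeError(PreimpactError):
    """A frame or index falls outside the recording it refers to."""


class TrainingError(PreimpactError):
    """Model training failed (e.g. the loss became non-finite)."""
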