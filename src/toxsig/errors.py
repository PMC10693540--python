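"""Exception hierarchy."""


class ToxsigError(Exception):
    """Base class for package errors."""


class ConfigurationError(ToxsigError):
    """Invalid simulation or pipeline configuration."""


class FormatError(ToxsigError):
    """Malformed input file (bad cell, duplicate id, wrong column count)."""


class DesignError(ToxsigError):
    """Statistical design cannot be fit (confounding, missing groups)."""


class StageError(ToxsigError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
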