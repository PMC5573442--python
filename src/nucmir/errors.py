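"""Exception hierarchy shared across the package."""


class NucmirError(Exception):
    """Base class for all package-specific errors."""


class ParseError(NucmirError):
    """An input file could not be parsed (bad cell, bad character, duplicate id)."""


class ConfigError(NucmirError):
    """Configuration or metadata is missing, malformed, or inconsistent."""


class ParameterError(NucmirError, ValueError):
    """A function argument is outside its valid domain."""


class PipelineError(NucmirError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
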