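"""Exception hierarchy for the detection pipeline."""


class McDetectError(Exception):
    """Base class for all package errors."""


class ParameterError(McDetectError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(McDetectError, ValueError):
    """An input file is readable but not in a supported layout."""


class SpecError(McDetectError, ValueError):
    """A phantom specification is internally inconsistent."""


class StageError(McDetectError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
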