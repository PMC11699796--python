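"""Exception types shared across the pipeline."""


class FermtxError(Exception):
    """Base class for all package-specific errors."""


class ParseError(FermtxError, ValueError):
    """A file could not be parsed; the message names the offending location."""


class ValidationError(FermtxError, ValueError):
    """An in-memory object violates a structural invariant."""


class PipelineStageError(FermtxError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
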