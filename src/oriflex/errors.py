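"""Exception types shared across the package."""


class OriflexError(Exception):
    """Base class for all oriflex errors."""


class ValidationError(OriflexError, ValueError):
    """Raised when an input object violates a structural invariant."""


class PipelineError(OriflexError, RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name and input."""

    def __init__(self, stage: str, message: str, path: str | None = None):
        self.stage = stage
        self.path = path
        where = f" [{path}]" if path else ""
        super().__init__(f"stage '{stage}'{where}: {message}")
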