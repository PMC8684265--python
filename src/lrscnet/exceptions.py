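"""Exception hierarchy used across the package."""


class LRSCError(Exception):
    """Base class for package errors."""


class ValidationError(LRSCError, ValueError):
    """An input violates a documented contract (shapes, labels, ranges)."""


class SchemaError(LRSCError, ValueError):
    """A manifest or config file is missing required structure."""


class DecodeError(LRSCError, IOError):
    """A raster file could not be read or decoded."""


class PipelineError(LRSCError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
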