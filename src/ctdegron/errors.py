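"""Exception hierarchy shared across the toolkit."""


class CtdegronError(Exception):
    """Base class for all toolkit errors."""


class InvalidArgumentError(CtdegronError, ValueError):
    """A caller-supplied argument violates a documented precondition."""


class FormatError(CtdegronError, ValueError):
    """An input file does not conform to its declared format."""


class DataError(CtdegronError, ValueError):
    """Input data is well-formed but unusable (empty, out of range, wrong vocabulary)."""


class ConfigError(CtdegronError, ValueError):
    """A pipeline configuration is invalid."""


class PipelineStageError(CtdegronError, RuntimeError):
    """Wraps a failure inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
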