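"""Exception hierarchy for the treatment-zone toolkit."""


class MczonesError(Exception):
    """Base class for all package errors."""


class FormatError(MczonesError):
    """Unreadable, unwritable, or unrecognized file format."""


class SchemaError(MczonesError):
    """A layer does not satisfy its declared attribute/geometry schema."""


class CRSError(MczonesError):
    """Unknown, missing, or mismatched coordinate reference system."""


class ConfigError(MczonesError):
    """Invalid pipeline configuration value or unknown key."""


class EmptyInputError(MczonesError):
    """An operation received an empty layer where features are required."""


class GenerationError(MczonesError):
    """The synthetic-county generator could not satisfy the requested parameters."""


class PipelineError(MczonesError):
    """A protocol stage failed; carries the 1-18 step number it maps to."""

    def __init__(self, step: int, message: str):
        self.step = step
        super().__init__(f"step {step}: {message}")
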