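"""Exception hierarchy shared across the package."""


class ChronomemError(Exception):
    """Base class for package errors."""


class ConfigError(ChronomemError, ValueError):
    """Invalid configuration value or structure."""


class DataError(ChronomemError, ValueError):
    """Invalid input data (bad shapes, ranges, schema violations)."""


class SchemaError(DataError):
    """A table does not match its declared schema."""


class SeparationError(DataError):
    """Complete separation detected while fitting a logistic model."""


class PipelineError(ChronomemError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
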