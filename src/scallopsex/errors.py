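"""Exception types shared across the pipeline."""


class ScallopsexError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ScallopsexError):
    """An input table is missing a required column or has an unusable layout."""


class ValidationError(ScallopsexError):
    """Row-level content violates an invariant (duplicate wells, bad enum, ...)."""


class InsufficientDataError(ScallopsexError):
    """Too few observations for the requested fit or test."""


class InvalidCurveError(ScallopsexError):
    """A standard curve with non-negative slope: Ct must fall as input rises."""


class ConfigError(ScallopsexError):
    """Inconsistent user configuration (e.g. disordered score thresholds)."""


class PipelineError(ScallopsexError):
    """Wraps a stage failure so the CLI can name the stage that died."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
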