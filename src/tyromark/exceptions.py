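"""Exception hierarchy shared across the package."""


class TyromarkError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TyromarkError):
    """A configuration value is invalid; the message names the field."""


class SchemaError(TyromarkError):
    """Tabular input does not match the expected columns/alignment."""


class InsufficientDataError(TyromarkError):
    """Too few observations for the requested computation."""


class DegenerateInputError(TyromarkError):
    """Input is degenerate (e.g. constant vector, single-class labels)."""


class EmptyResultError(TyromarkError):
    """An upstream stage produced an empty result the caller refuses to use."""


class SplitError(TyromarkError):
    """No valid train/test partition could be drawn."""


class StageError(TyromarkError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
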