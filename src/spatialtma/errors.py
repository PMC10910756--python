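"""Exception hierarchy shared across pipeline stages."""


class SpatialTMAError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(SpatialTMAError):
    """Invalid user-supplied configuration (bad proportions, counts, thresholds)."""


class SchemaError(SpatialTMAError):
    """Input table does not satisfy the required schema."""

    def __init__(self, message: str, missing: list[str] | None = None):
        super().__init__(message)
        self.missing = missing or []


class GenerationError(SpatialTMAError):
    """Synthetic generation could not satisfy the requested geometry."""


class NoEventsError(SpatialTMAError):
    """Survival analysis requested but no uncensored events are present."""


class EmptyTableError(SpatialTMAError):
    """A stage received or produced an empty cell table."""
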