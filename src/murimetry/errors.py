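"""Package-wide exception types."""


class MurimetryError(Exception):
    """Base class for all package errors."""


class ConfigError(MurimetryError, ValueError):
    """A configuration object violates its invariants."""


class PlacementError(MurimetryError, RuntimeError):
    """Mice could not be placed without overlap within the attempt budget."""


class SchemaError(MurimetryError, ValueError):
    """An on-disk file violates the expected schema."""


class TrainingDivergedError(MurimetryError, RuntimeError):
    """A non-finite loss was encountered during training."""
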