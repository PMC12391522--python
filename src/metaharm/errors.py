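"""Exception hierarchy shared across the package."""


class MetaharmError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MetaharmError, ValueError):
    """A file does not have the expected structure (missing columns, bad dialect)."""


class ValidationError(MetaharmError, ValueError):
    """Structurally readable input violates a corpus/model invariant."""


class EmbeddingBackendUnavailable(MetaharmError, RuntimeError):
    """An optional embedding backend (e.g. a transformer model) is not installed."""


class ModelFormatError(MetaharmError, ValueError):
    """A serialized model file is corrupted or has an incompatible version."""
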