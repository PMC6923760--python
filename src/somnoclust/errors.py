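"""Exception types shared across the pipeline stages."""


class SomnoclustError(Exception):
    """Base class for all package errors."""


class ValidationError(SomnoclustError, ValueError):
    """A configuration or argument violates its invariants."""


class SchemaError(SomnoclustError, ValueError):
    """An input table is missing required columns or has bad cells."""


class InsufficientDataError(SomnoclustError, ValueError):
    """Too little data for the requested operation (e.g. short series)."""


class TrainingError(SomnoclustError, RuntimeError):
    """Autoencoder optimisation diverged (non-finite loss)."""


class ClusteringError(SomnoclustError, RuntimeError):
    """Clustering cannot produce a usable partition."""


class SequencingError(SomnoclustError, ValueError):
    """Window labels cannot be assembled into a contiguous sequence."""
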