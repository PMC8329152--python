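"""Exception hierarchy shared across the pipeline."""


class NoduleFuseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NoduleFuseError, ValueError):
    """Invalid configuration or parameter value."""


class EmptyDatasetError(NoduleFuseError, ValueError):
    """A dataset construction step produced no usable records."""


class SplitError(NoduleFuseError, ValueError):
    """Train/test splitting could not be performed."""


class GenerationError(NoduleFuseError, ValueError):
    """Synthetic nodule rendering failed (e.g. nodule larger than the grid)."""


class AnnotationParseError(NoduleFuseError, ValueError):
    """Malformed annotation XML."""


class GeometryError(NoduleFuseError, ValueError):
    """Contour or box geometry falls outside the image grid."""


class ExtractionError(NoduleFuseError, ValueError):
    """Bounding-box extraction failed (e.g. empty mask)."""


class LabelingError(NoduleFuseError, ValueError):
    """Pseudo-labeling could not be performed."""


class TrainingError(NoduleFuseError, ValueError):
    """Model training preconditions violated."""
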