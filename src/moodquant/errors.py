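"""Exception hierarchy shared across the pipeline."""


class MoodQuantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MoodQuantError):
    """Invalid cohort, preprocessing or model configuration."""


class SchemaError(MoodQuantError):
    """Input data does not match the expected schema."""


class ValidationError(MoodQuantError):
    """Values are outside their allowed range."""


class EmptyOutputError(MoodQuantError):
    """An operation would produce no output (e.g. recording shorter than one segment)."""


class DecompositionDepthError(MoodQuantError):
    """Series too short for the requested wavelet decomposition depth."""


class DegeneratePCAError(MoodQuantError):
    """PCA on a constant (zero-variance) matrix."""


class ClassificationError(MoodQuantError):
    """Trend classification impossible (too few sessions per week)."""


class AlignmentError(MoodQuantError):
    """No feature rows could be matched to diary values."""


class ParameterError(MoodQuantError):
    """Invalid model hyper-parameter."""


class UndefinedCorrelationError(MoodQuantError):
    """Pearson correlation undefined (constant input)."""


class AggregationError(MoodQuantError):
    """Segment aggregation received no input."""


class CatalogError(MoodQuantError):
    """Unknown feature name."""


class InferenceIntegrityError(MoodQuantError):
    """A rule set failed to cover the feature space (no rule fired)."""


class DependencyError(MoodQuantError):
    """A pipeline stage is missing a required upstream artifact."""
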