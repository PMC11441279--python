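"""Exception hierarchy shared across the package."""


class CircDrugError(Exception):
    """Base class for all package-specific errors."""


class IdentifierError(CircDrugError):
    """Duplicate or inconsistent entity identifiers."""


class ParseError(CircDrugError):
    """A file could not be parsed into the expected structure."""


class RecordError(CircDrugError):
    """A single record (sequence, drug) is malformed."""


class ConfigurationError(CircDrugError):
    """A parameter is outside its valid range."""


class DimensionError(CircDrugError):
    """Matrix shapes or identifier lists do not line up."""


class ComputationError(CircDrugError):
    """A numerical quantity is undefined for the given input."""


class NormalizationError(CircDrugError):
    """A row cannot be normalized (all-zero off-diagonal mass)."""


class TrainingError(CircDrugError):
    """Training produced a non-finite loss."""


class SamplingError(CircDrugError):
    """Not enough negatives available for balanced sampling."""


class EvaluationError(CircDrugError):
    """Metrics are undefined (e.g. single-class fold)."""


class CandidateLookupError(CircDrugError):
    """An entity id was not found in the dataset."""
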