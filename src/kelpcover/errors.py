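"""Exception hierarchy shared across the package.

Validation errors (bad data) are distinguished from configuration errors
(bad parameters) so the CLI can map them to distinct exit codes.
"""


class KelpcoverError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(KelpcoverError):
    """Input data violates an invariant (duplicates, misalignment, ...)."""


class ConfigurationError(KelpcoverError):
    """A parameter or config value is malformed or out of range."""


class HierarchyLookupError(KelpcoverError, KeyError):
    """A node id is not present in the hierarchy tree."""


class PolicyError(ConfigurationError):
    """A training policy cannot be applied to the requested node."""


class TrainingError(KelpcoverError):
    """Training preconditions are not met (single class, tiny strata, ...)."""


class StratificationError(TrainingError):
    """A class has fewer samples than the number of CV folds."""


class CompatibilityError(KelpcoverError):
    """Feature matrix and model disagree on extractor or dimensionality."""


class CoordinateError(ValidationError):
    """A pixel coordinate falls outside its image."""


class ExtractorUnavailableError(KelpcoverError):
    """The requested feature extractor cannot run in this installation."""
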