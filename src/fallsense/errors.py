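"""Exception hierarchy.

Every error raised by the package derives from :class:`FallsenseError`,
so callers can catch one base class at pipeline boundaries.
"""


class FallsenseError(Exception):
    """Base class for all package errors."""


class FormatError(FallsenseError):
    """A file does not conform to the documented on-disk dialect."""


class IntegrityError(FallsenseError):
    """Sample stream violates the regular 40 Hz time grid."""


class AnnotationError(FallsenseError):
    """Event annotation inconsistent with its invariants."""


class ValidationError(FallsenseError):
    """Input data or parameters violate a documented contract."""


class ParameterError(ValidationError):
    """A single parameter is outside its allowed set."""


class ConfigurationError(FallsenseError):
    """Unknown subtype or malformed generator/pipeline configuration."""


class RegistryError(FallsenseError):
    """Feature name unknown to the canonical feature registry."""


class StratificationError(FallsenseError):
    """Too few samples in a class to stratify a split or fold."""


class BackendUnavailableError(FallsenseError):
    """Requested boosted-tree backend is not installed."""
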