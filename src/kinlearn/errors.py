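"""Exception hierarchy shared across the package."""


class KinlearnError(Exception):
    """Base class for all package-specific errors."""


class DuplicateNameError(KinlearnError):
    """A name collides with an existing component in the model namespace."""


class UnknownReferenceError(KinlearnError):
    """A referenced component name does not exist."""


class DependencyError(KinlearnError):
    """Invalid dependency structure (cycle, dynamic stoichiometry, ...)."""


class NumericError(KinlearnError):
    """A numerical evaluation produced a non-finite or invalid result."""


class ValidationError(KinlearnError):
    """An input object violates its contract."""


class MappingError(KinlearnError):
    """Shared-parameter map is not a bijection onto the free parameters."""


class EmptyModelError(KinlearnError):
    """Operation requires a nonempty model."""


class SummaryError(KinlearnError):
    """Ensemble summary requested with zero successful members."""


class FitError(KinlearnError):
    """Distribution fitting failed (e.g. empty table)."""
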