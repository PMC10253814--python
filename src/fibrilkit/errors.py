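"""Exception hierarchy for fibrilkit.

Every anticipated failure mode raises a subclass of :class:`FibrilkitError`
so callers can distinguish validation problems, degenerate inputs, and
numerical failures from programming errors.
"""


class FibrilkitError(Exception):
    """Base class for all fibrilkit errors."""


class ValidationError(FibrilkitError):
    """Input data violate a documented invariant (shapes, ordering, finiteness)."""


class DegenerateParameterError(FibrilkitError):
    """Model parameters collapse the functional form (e.g. t_half == t_lag)."""


class NoTransitionError(FibrilkitError):
    """A kinetic trace shows no sigmoidal rise; there is nothing to fit."""


class OrderingError(FibrilkitError):
    """Kinetic times violate the required ordering t_half > t_lag."""


class ZeroRangeError(FibrilkitError):
    """Fitted plateaus coincide (y2 == y1); normalization is undefined."""


class AlignmentError(FibrilkitError):
    """Replicate traces do not share a common time grid."""


class GroupingError(FibrilkitError):
    """A ranking call mixed conditions from different concentrations."""


class NoObjectsError(FibrilkitError):
    """A grain table or height distribution contains no objects."""


class InsufficientSampleError(FibrilkitError):
    """Too few objects for a resampling-based uncertainty estimate."""


class SaturationWarning(UserWarning):
    """Segmentation threshold lies below the map minimum: everything is one object."""


class ResolutionError(FibrilkitError):
    """A smoothing window is wider than the available data."""


class EmptyModelError(FibrilkitError):
    """A peak model has zero total area; percentages are undefined."""


class ManifestError(FibrilkitError):
    """A study manifest is structurally invalid."""
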