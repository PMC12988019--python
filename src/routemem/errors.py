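"""Named error types.

Validation in this package is total: every malformed input maps to one of
these exceptions rather than a silently truncated result.
"""


class RoutememError(Exception):
    """Base class for all package errors."""


class TrackFormatError(RoutememError):
    """Track file unreadable or missing required columns/elements."""


class DegenerateTrackError(RoutememError):
    """Fewer than two valid fixes, or an operation removed every fix."""


class TrackOrderingError(RoutememError):
    """Timestamps not strictly increasing (duplicates are corruption, not ties)."""


class MetadataError(RoutememError):
    """Release-metadata table violates an invariant (reported with row numbers)."""


class NonDepartureError(RoutememError):
    """Track never leaves the release radius; no homing segment exists."""


class NonHomingError(RoutememError):
    """Track never enters the home radius; excluded from analysis."""


class CannotCompareError(RoutememError):
    """Two tracks lack a common (wall-clock) time base."""


class MissingBaselineError(RoutememError):
    """A route-memory metric was requested against an empty baseline set."""


class RankDeficiencyError(RoutememError):
    """A model factor has an empty level after subsetting."""


class ConfigError(RoutememError):
    """Inconsistent simulation or pipeline configuration."""
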