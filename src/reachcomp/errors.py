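"""Exception hierarchy for reachcomp.

All package-specific failures derive from :class:`ReachcompError` so callers
can catch everything in one clause while tests can assert precise subtypes.
"""


class ReachcompError(Exception):
    """Base class for all reachcomp errors."""


class TrialFormatError(ReachcompError):
    """Structural problem in a trial table (missing metadata, bad header)."""


class TrialParseError(ReachcompError):
    """A cell in a trial table could not be parsed; names row and column."""


class MarkerMappingError(ReachcompError):
    """A required marker could not be resolved from a C3D label map."""


class UnitError(ReachcompError):
    """Positions stored in a unit the reader does not understand."""


class ParameterError(ReachcompError):
    """An out-of-range analysis parameter (e.g. cutoff above Nyquist)."""


class NoMovementError(ReachcompError):
    """Peak end-effector speed is below the movement floor."""


class MissingDataError(ReachcompError):
    """A marker needed by the computation is absent or NaN where evaluated."""


class DegenerateTrialError(ReachcompError):
    """Total displacement too small for percentages to be meaningful."""


class MetadataError(ReachcompError):
    """A metadata field required by the requested mode is missing."""


class CohortDataError(ReachcompError):
    """Cohort table lacks the rows or groups needed for an aggregate."""
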