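"""Exception hierarchy for the pipeline.

Every user-facing failure mode raises a subclass of :class:`AdrenADCError`,
so callers can catch one base type at pipeline level while tests pin the
specific condition.
"""


class AdrenADCError(Exception):
    """Base class for all package errors."""


class ValidationError(AdrenADCError, ValueError):
    """An input violated a documented precondition or type invariant."""


class FitFailureError(AdrenADCError):
    """A voxel had fewer than two usable (positive-signal) b-value points."""


class SeedRejectionError(AdrenADCError):
    """An interior seed voxel lies below the segmentation threshold."""


class RegistrationError(AdrenADCError):
    """Two grids do not describe overlapping physical fields of view."""


class MeasurementError(AdrenADCError):
    """A masked voxel could not be measured (empty mask or failed fit)."""


class DegenerateTableError(AdrenADCError):
    """An agreement table has no between-subject variance; ICC is undefined."""


class ClassificationError(AdrenADCError):
    """A subject cannot be assigned to a pubertal group."""
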