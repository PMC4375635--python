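"""Exception hierarchy for the hippoquant pipeline.

Every stage raises a subclass of :class:`HippoquantError` so callers can
distinguish pipeline failures from programming errors.
"""


class HippoquantError(Exception):
    """Base class for all hippoquant errors."""


class SizingError(HippoquantError):
    """Image matrix too small to contain the phantom geometry."""


class GridMismatchError(HippoquantError):
    """Two volumes that must share shape and voxel spacing do not."""


class ConfigurationError(HippoquantError):
    """Invalid acquisition, tissue or pipeline configuration."""


class CohortValidationError(HippoquantError):
    """A CohortSpec violates its invariants (infeasible fractions etc.)."""


class ReferenceRegionError(HippoquantError):
    """Empty or invalid white-matter reference region for normalisation."""


class PlacementError(HippoquantError):
    """ROI auto-placement could not satisfy the placement policy."""


class MeasurementError(HippoquantError):
    """ROI measurement refused (e.g. invalid T2 voxels inside the ROI)."""


class InsufficientDataError(HippoquantError):
    """Too few measurements to derive a statistic."""
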