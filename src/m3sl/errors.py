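"""Exception hierarchy for the segmentation pipeline.

Every contract violation raises a subclass of :class:`M3SLError` so callers can
catch pipeline failures without masking programming errors.
"""


class M3SLError(Exception):
    """Base class for all package-specific errors."""


class DimensionalityError(M3SLError):
    """Input grid has the wrong number of axes (e.g. a 4D NIfTI)."""


class SizeError(M3SLError):
    """An axis exceeds the allowed size (e.g. padding target too small)."""


class NormalizationError(M3SLError):
    """Degenerate percentile range, or re-normalizing a normalized volume."""


class TilingError(M3SLError):
    """A volume cannot be tiled into patches, or patches overlap."""


class AlignmentError(M3SLError):
    """Two grids that must share a voxel lattice do not."""


class DegenerateInputError(M3SLError):
    """Input carries no usable signal (e.g. all-empty rater masks)."""


class ArchitectureError(M3SLError):
    """Model spec is internally inconsistent (e.g. input edge not divisible)."""


class ShapeError(M3SLError):
    """Tensor shape mismatch at a model or loss boundary."""


class SplitError(M3SLError):
    """Requested data split is infeasible (stratum too small, bad fractions)."""


class StatsError(M3SLError):
    """Statistical routine given groups it cannot handle (e.g. n < 2)."""


class GenerationError(M3SLError):
    """Synthetic phantom target is infeasible for the requested geometry."""


class PipelineConfigError(M3SLError):
    """A curriculum stage is missing its required inputs."""


class UndefinedMetricError(M3SLError):
    """A metric has no defined value for the given counts (all zero)."""
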