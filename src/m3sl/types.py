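"""Core in-memory containers shared across the pipeline.

A :class:`VolumeImage` is a 3D scalar intensity grid with voxel spacing and
subject/scanner metadata; a :class:`BinaryMask` is a boolean lesion grid on
the same lattice, tagged with its provenance tier (``bronze`` automated /
``silver`` consensus / ``gold`` expert / ``predicted``).  A :class:`PatchSet`
is a non-overlapping cubic tiling of a padded volume, the unit the network
trains on.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import AlignmentError

MASK_ROLES = ("bronze", "silver", "gold", "predicted", "icv")

#: Mapping from anatomical orientation name to the volume axis its slices are
#: perpendicular to.  Axis order convention: (sagittal, coronal, axial) =
#: (x, y, z), i.e. axis 0 varies left-right.
ORIENTATION_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass
class VolumeImage:
    """3D intensity volume plus acquisition metadata."""

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""
    scanner_label: str = "synthetic"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            from .errors import DimensionalityError

            raise DimensionalityError(
                f"VolumeImage requires a 3D grid, got {self.data.ndim} axes "
                f"with shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, **changes) -> "VolumeImage":
        """Copy of this volume with new voxel data (metadata preserved)."""
        return replace(self, data=data, **changes)


@dataclass
class BinaryMask:
    """Boolean lesion grid aligned voxel-for-voxel with a VolumeImage."""

    data: np.ndarray
    role: str = "gold"
    subject_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            from .errors import DimensionalityError

            raise DimensionalityError(
                f"BinaryMask requires a 3D grid, got {arr.ndim} axes"
            )
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(
                    f"mask values must be binary 0/1, found {uniq[:5]}"
                )
            arr = arr.astype(bool)
        self.data = arr
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}; expected one of {MASK_ROLES}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


def check_aligned(a, b, what: str = "grids") -> None:
    """Raise AlignmentError unless the two grids share a shape."""
    sa = a.shape if isinstance(a, np.ndarray) else a.data.shape
    sb = b.shape if isinstance(b, np.ndarray) else b.data.shape
    if sa != sb:
        raise AlignmentError(f"{what} are misaligned: {sa} vs {sb}")


@dataclass
class PatchSet:
    """Ordered non-overlapping cubic tiles of a (padded) parent grid.

    ``origins[i]`` is the 0-based corner of ``patches[i]`` in parent index
    space; each patch spans the half-open box [origin, origin+edge) and every
    origin is a multiple of ``edge`` along each axis.
    """

    patches: list  # list of 3D arrays, each edge^3
    origins: list  # list of (i, j, k) int tuples
    edge: int
    parent_shape: Tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(zip(self.origins, self.patches))


@dataclass
class SubjectRecord:
    """One cohort member: identity, clinical stage, scanner, demographics,
    and references to its volume and masks (in-memory or on-disk)."""

    subject_id: str
    stage: str  # CN | MCI | AD
    scanner_label: str
    age: float
    sex: str  # "M" | "F"
    annotated: bool = True  # False => gold mask withheld from training
    volume: Optional[VolumeImage] = None
    gold: Optional[BinaryMask] = None
    icv: Optional[BinaryMask] = None
    bronze: list = field(default_factory=list)  # list[BinaryMask]
    silver: Optional[BinaryMask] = None
    paths: dict = field(default_factory=dict)  # on-disk locations when saved
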