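"""NIfTI I/O, dimension standardization, intensity normalization, patching.

The preparation pipeline mirrors common practice for 2D-acquired FLAIR
volumes: scans arrive as 256x256 in-plane grids with a variable number of
slices, are zero-padded to a cube, tiled into equal cubic patches, and the
patches that contain at least one labeled lesion voxel are kept for training
(class-imbalance control).  Intensity is mapped to [0, 1] by percentile
scaling: the default dialect scales the 0th-98th percentile range and clips
the bright tail; the fat-suppressed dialect (for scanners whose FLAIR
contrast differs) is a pure 0th-100th min-max.
"""
from __future__ import annotations

import itertools
from typing import Iterable, List, Tuple

import nibabel as nib
import numpy as np

from .errors import (
    AlignmentError,
    DimensionalityError,
    NormalizationError,
    SizeError,
    TilingError,
)
from .types import ORIENTATION_AXES, BinaryMask, PatchSet, VolumeImage, check_aligned

DEFAULT_CUBE_EDGE = 256
DEFAULT_PATCH_EDGE = 64
NORM_DIALECTS = {"default": (0.0, 98.0), "fat_suppressed": (0.0, 100.0)}


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def load_volume(path, subject_id: str = "", scanner_label: str = "") -> VolumeImage:
    """Load a 3D scalar NIfTI volume (.nii or .nii.gz).

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    DimensionalityError
        If the image is not 3D (a trailing singleton 4th axis is squeezed,
        matching scanner exports that store 3D data as Nx x Ny x Nz x 1).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D scalar image, got {data.ndim} axes "
            f"with shape {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(
        data=np.asarray(data, dtype=np.float64),
        spacing=spacing,
        subject_id=subject_id,
        scanner_label=scanner_label or "unknown",
    )


def load_mask(path, role: str = "gold", subject_id: str = "") -> BinaryMask:
    """Load a binary mask stored as an 8-bit {0,1} NIfTI."""
    vol = load_volume(path, subject_id=subject_id)
    return BinaryMask(data=vol.data > 0.5, role=role, subject_id=subject_id)


def save_volume(v: VolumeImage, path) -> None:
    affine = np.diag(list(v.spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), affine), str(path))


def save_mask(m: BinaryMask, path, spacing=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(m.data.astype(np.uint8), affine), str(path))


# ---------------------------------------------------------------------------
# Dimension standardization
# ---------------------------------------------------------------------------

def pad_to_cube(v: VolumeImage, target_edge: int = DEFAULT_CUBE_EDGE) -> VolumeImage:
    """Zero-pad a volume to ``target_edge``^3 by appending blank voxels.

    Padding is appended at the high-index end of each axis so that every
    original voxel keeps its coordinates — masks padded the same way stay
    aligned with their volume.
    """
    shape = v.data.shape
    for ax, n in enumerate(shape):
        if n > target_edge:
            raise SizeError(
                f"axis {ax} has length {n} > target edge {target_edge}; "
                "cannot pad a volume down"
            )
    pad = [(0, target_edge - n) for n in shape]
    out = np.pad(v.data, pad, mode="constant", constant_values=0)
    return v.with_data(out)


def pad_mask_to_cube(m: BinaryMask, target_edge: int = DEFAULT_CUBE_EDGE) -> BinaryMask:
    """Mask counterpart of :func:`pad_to_cube` (appended voxels are False)."""
    as_vol = VolumeImage(data=m.data.astype(np.uint8))
    padded = pad_to_cube(as_vol, target_edge)
    return BinaryMask(data=padded.data.astype(bool), role=m.role, subject_id=m.subject_id)


# ---------------------------------------------------------------------------
# Intensity normalization
# ---------------------------------------------------------------------------

def normalize_intensity(
    v: VolumeImage, lo_pct: float = 0.0, hi_pct: float = 98.0
) -> VolumeImage:
    """Map the [lo_pct, hi_pct] intensity percentile range linearly to [0, 1].

    Values above the high percentile are clipped to 1.0 (the default dialect
    clips the bright tail above the 98th percentile); ``hi_pct=100`` gives a
    pure min-max scaling with nothing to clip.  A constant volume maps to all
    zeros.
    """
    if v.normalized:
        raise NormalizationError(f"volume {v.subject_id!r} is already normalized")
    if not hi_pct > lo_pct:
        raise NormalizationError(f"need hi_pct > lo_pct, got ({lo_pct}, {hi_pct})")
    data = np.asarray(v.data, dtype=np.float64)
    lo, hi = np.percentile(data, [lo_pct, hi_pct])
    if hi == lo:
        if data.min() == data.max():
            return v.with_data(np.zeros_like(data), normalized=True)
        raise NormalizationError(
            f"degenerate percentile range on non-constant data: "
            f"P{lo_pct} == P{hi_pct} == {lo}"
        )
    out = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    return v.with_data(out, normalized=True)


def normalize_dialect(v: VolumeImage, dialect: str = "default") -> VolumeImage:
    """Normalize using a named dialect: ``default`` (0-98th, clipped tail) or
    ``fat_suppressed`` (0-100th pure min-max)."""
    try:
        lo, hi = NORM_DIALECTS[dialect]
    except KeyError:
        raise NormalizationError(
            f"unknown normalization dialect {dialect!r}; "
            f"expected one of {sorted(NORM_DIALECTS)}"
        ) from None
    return normalize_intensity(v, lo, hi)


# ---------------------------------------------------------------------------
# Patching
# ---------------------------------------------------------------------------

def _tile_origins(shape: Tuple[int, ...], edge: int) -> List[Tuple[int, int, int]]:
    for ax, n in enumerate(shape):
        if n % edge != 0:
            raise TilingError(
                f"axis {ax} length {n} not divisible by patch edge {edge} "
                f"(remainder {n % edge})"
            )
    ranges = [range(0, n, edge) for n in shape]
    return [tuple(o) for o in itertools.product(*ranges)]


def patchify(grid: np.ndarray, edge: int = DEFAULT_PATCH_EDGE) -> PatchSet:
    """Tile a 3D grid into non-overlapping cubic patches of side ``edge``.

    Origins are emitted in lexicographic order; a 256-cube at edge 64 yields
    exactly 4^3 = 64 patches.
    """
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise DimensionalityError(f"patchify requires a 3D grid, got {grid.ndim} axes")
    origins = _tile_origins(grid.shape, edge)
    patches = [
        grid[o[0] : o[0] + edge, o[1] : o[1] + edge, o[2] : o[2] + edge].copy()
        for o in origins
    ]
    return PatchSet(patches=patches, origins=origins, edge=edge, parent_shape=grid.shape)


def filter_lesion_patches(vols: PatchSet, masks: PatchSet) -> Tuple[PatchSet, PatchSet]:
    """Keep only patch pairs whose mask patch contains >= 1 True voxel.

    Order is preserved and the surviving origins are recorded in both
    returned sets, so a filtered prediction can still be reconstructed into
    the parent volume (missing tiles are zero-filled).
    """
    if vols.edge != masks.edge or vols.parent_shape != masks.parent_shape:
        raise AlignmentError(
            f"volume and mask patch sets disagree: edge {vols.edge} vs "
            f"{masks.edge}, parent {vols.parent_shape} vs {masks.parent_shape}"
        )
    if list(vols.origins) != list(masks.origins):
        raise AlignmentError("volume and mask patch sets have different origins")
    keep = [i for i, p in enumerate(masks.patches) if np.any(p)]
    return (
        PatchSet(
            patches=[vols.patches[i] for i in keep],
            origins=[vols.origins[i] for i in keep],
            edge=vols.edge,
            parent_shape=vols.parent_shape,
        ),
        PatchSet(
            patches=[masks.patches[i] for i in keep],
            origins=[masks.origins[i] for i in keep],
            edge=masks.edge,
            parent_shape=masks.parent_shape,
        ),
    )


def reconstruct(p: PatchSet, dtype=None) -> np.ndarray:
    """Place patches back at their origins; absent tiles stay zero/False.

    Inverse of :func:`patchify` when no patch was filtered out.
    """
    if dtype is None:
        dtype = p.patches[0].dtype if p.patches else np.float64
    out = np.zeros(p.parent_shape, dtype=dtype)
    seen = set()
    e = p.edge
    for o, patch in zip(p.origins, p.patches):
        if tuple(o) in seen:
            raise TilingError(f"overlapping patch origin {o}")
        seen.add(tuple(o))
        out[o[0] : o[0] + e, o[1] : o[1] + e, o[2] : o[2] + e] = patch
    return out


# ---------------------------------------------------------------------------
# Orientation slicing (2.5D)
# ---------------------------------------------------------------------------

def orientation_slices(grid: np.ndarray, axis: str) -> np.ndarray:
    """Stack of 2D slices perpendicular to the named anatomical axis.

    Returns an array of shape (n_slices, h, w), slice index first, ordered by
    position along the axis.  ``restack`` inverts the operation.
    """
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise DimensionalityError(f"expected a 3D grid, got {grid.ndim} axes")
    try:
        ax = ORIENTATION_AXES[axis]
    except KeyError:
        raise ValueError(
            f"unknown orientation {axis!r}; expected one of {sorted(ORIENTATION_AXES)}"
        ) from None
    return np.moveaxis(grid, ax, 0)


def restack(slices: np.ndarray, axis: str) -> np.ndarray:
    """Rebuild a 3D grid from its :func:`orientation_slices` stack."""
    slices = np.asarray(slices)
    if slices.ndim != 3:
        raise DimensionalityError(f"expected a slice stack, got {slices.ndim} axes")
    try:
        ax = ORIENTATION_AXES[axis]
    except KeyError:
        raise ValueError(
            f"unknown orientation {axis!r}; expected one of {sorted(ORIENTATION_AXES)}"
        ) from None
    return np.moveaxis(slices, 0, ax)
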