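"""Segmentation evaluation metrics.

Because lesion voxels are a tiny minority (true-negative fraction ~0.98),
evaluation uses metrics that ignore true negatives: precision P = TP/(TP+FP),
recall R = TP/(TP+FN), F-measure F = 2PR/(P+R) = 2TP/(2TP+FN+FP), and
IoU = TP/(TP+FP+FN), plus the 95th-percentile Hausdorff distance between
mask boundaries (HD95) and the normalized lesion volume nWMH (% of
intracranial volume).

Degenerate-mask conventions (evaluation must be total over a cohort):
if prediction and reference are both empty, P = R = F = IoU = 1.0; if
exactly one is empty, F = IoU = 0 (and the metric whose denominator is zero
is 0).  HD95 of an empty mask is undefined and recorded as NaN — excluded
from group means but counted in reports.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import AlignmentError
from .types import BinaryMask, check_aligned

#: 6-connectivity structuring element (face neighbors only)
_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    """Per-subject evaluation row, aggregable by stage/scanner/variant."""

    subject_id: str
    precision: float
    recall: float
    f_measure: float
    iou: float
    hd95: float  # mm (voxels at unit spacing); NaN when undefined
    nwmh: float  # % of intracranial volume
    stage: str = ""
    scanner: str = ""
    variant: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def confusion_counts(pred: BinaryMask, gt: BinaryMask) -> ConfusionCounts:
    """Exact voxel-wise confusion tabulation of aligned masks."""
    check_aligned(pred, gt, "pred/gt masks")
    p, g = pred.data, gt.data
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def precision(c: ConfusionCounts) -> float:
    if c.tp + c.fp == 0:
        return 1.0 if c.fn == 0 else 0.0
    return c.tp / (c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        return 1.0 if c.fp == 0 else 0.0
    return c.tp / (c.tp + c.fn)


def f_measure(c: ConfusionCounts) -> float:
    den = 2 * c.tp + c.fn + c.fp
    if den == 0:
        return 1.0  # both masks empty
    return 2 * c.tp / den


def iou(c: ConfusionCounts) -> float:
    den = c.tp + c.fp + c.fn
    if den == 0:
        return 1.0  # both masks empty
    return c.tp / den


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one background face-neighbor."""
    eroded = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    return mask & ~eroded


def surface_distances(
    a: np.ndarray, b: np.ndarray, spacing: Sequence[float] = (1.0, 1.0, 1.0)
) -> Tuple[np.ndarray, np.ndarray]:
    """Directed boundary distances (a->b, b->a), spacing-aware.

    Uses a Euclidean distance transform of each boundary set, sampled at the
    other boundary's voxels.
    """
    ba, bb = _boundary(a), _boundary(b)
    dt_to_b = ndimage.distance_transform_edt(~bb, sampling=spacing)
    dt_to_a = ndimage.distance_transform_edt(~ba, sampling=spacing)
    return dt_to_b[ba], dt_to_a[bb]


def hd95(
    pred: BinaryMask,
    gt: BinaryMask,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    pooled: bool = True,
) -> float:
    """95th-percentile Hausdorff distance between mask boundaries.

    Default is the symmetric pooled form: both directed surface-distance
    sets are pooled and the 95th percentile (linear interpolation) of the
    pooled distribution is returned.  ``pooled=False`` gives the
    max-of-directed-95th-percentiles alternative.  Returns NaN if either
    mask is empty (undefined distance; callers exclude it from means).
    """
    check_aligned(pred, gt, "pred/gt masks")
    p, g = pred.data, gt.data
    if not p.any() or not g.any():
        return float("nan")
    d_ab, d_ba = surface_distances(p, g, spacing)
    if pooled:
        return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def nwmh(
    mask: BinaryMask,
    icv_mask: BinaryMask,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
) -> float:
    """Lesion volume as a percentage of intracranial volume."""
    check_aligned(mask, icv_mask, "lesion/ICV masks")
    icv = int(icv_mask.data.sum())
    if icv == 0:
        raise ValueError("ICV mask is empty; nWMH undefined")
    # spacing cancels in the ratio for a shared lattice, kept for clarity
    voxvol = float(np.prod(spacing))
    return 100.0 * (int(mask.data.sum()) * voxvol) / (icv * voxvol)


def evaluate_pair(
    pred: BinaryMask,
    gt: BinaryMask,
    icv: Optional[BinaryMask] = None,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    subject_id: str = "",
    stage: str = "",
    scanner: str = "",
    variant: str = "",
) -> MetricReport:
    """All per-subject metrics for one prediction/reference pair."""
    c = confusion_counts(pred, gt)
    return MetricReport(
        subject_id=subject_id or gt.subject_id,
        precision=precision(c),
        recall=recall(c),
        f_measure=f_measure(c),
        iou=iou(c),
        hd95=hd95(pred, gt, spacing),
        nwmh=nwmh(pred, icv, spacing) if icv is not None else float("nan"),
        stage=stage,
        scanner=scanner,
        variant=variant,
    )


def reports_to_frame(reports: List[MetricReport]):
    """MetricReports as a pandas DataFrame (one row per subject)."""
    import pandas as pd

    return pd.DataFrame([r.to_dict() for r in reports])
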