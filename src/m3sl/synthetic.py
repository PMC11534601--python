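"""Desk-scale synthetic cohorts: phantom FLAIR-like volumes, gold lesion
masks, simulated automated raters, and demographic/scanner metadata.

A phantom is an ellipsoidal "intracranial" region (40-60% of the cube)
filled with a smooth tissue background, plus hyperintense ellipsoidal blob
lesions whose total volume is calibrated to a clinical-stage-dependent
normalized lesion volume (nWMH, % of intracranial volume): cognitively
normal subjects carry the least lesion load and Alzheimer's-disease
subjects the most.  Scanner labels A-E modulate global contrast gain/offset
and noise, emulating multi-scanner acquisition; two scanners use the
fat-suppressed contrast dialect (pure min-max normalization downstream).

Simulated raters corrupt the gold mask with a per-voxel sensitivity /
specificity model (false positives confined to the intracranial region —
automated tools do not hallucinate lesions outside the head) plus optional
stochastic boundary jitter, standing in for the three automated lesion
toolboxes whose outputs form the "bronze" tier.

The generator does not attempt anatomically realistic MRI (no tissue
classes, partial-volume or k-space effects); it reproduces only the
statistical structure the pipeline relies on.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, GenerationError
from .types import BinaryMask, SubjectRecord, VolumeImage

#: stage-dependent target nWMH ranges (% of ICV), ordered CN < MCI < AD
STAGE_NWMH_RANGES: Dict[str, Tuple[float, float]] = {
    "CN": (0.01, 0.10),
    "MCI": (0.10, 0.30),
    "AD": (0.30, 1.50),
}

#: per-scanner (contrast gain, offset, noise sd); A is the reference scanner
SCANNER_CONTRAST: Dict[str, Tuple[float, float, float]] = {
    "A": (1.00, 0.00, 0.040),
    "B": (1.10, 0.02, 0.050),
    "C": (0.90, 0.05, 0.040),
    "D": (1.20, -0.02, 0.060),
    "E": (0.95, 0.03, 0.050),
}

#: scanners whose FLAIR contrast behaves as fat-suppressed (min-max dialect)
FAT_SUPPRESSED_SCANNERS = frozenset({"C", "E"})

#: default simulated raters: (sensitivity, specificity, boundary_jitter)
DEFAULT_RATER_PARAMS = ((0.90, 0.995, 1), (0.75, 0.999, 2), (0.85, 0.990, 1))

DEFAULT_STAGE_MIX = {"CN": 0.45, "MCI": 0.35, "AD": 0.20}
DEFAULT_SCANNER_MIX = {"A": 0.40, "B": 0.20, "C": 0.15, "D": 0.15, "E": 0.10}
DEFAULT_UNANNOTATED_FRACTION = 0.53  # un-annotated majority of the cohort


@dataclass
class PhantomSpec:
    """Recipe for one synthetic subject volume."""

    cube_edge: int = 64
    stage: str = "CN"
    scanner_label: str = "A"
    target_nwmh_range: Optional[Tuple[float, float]] = None  # default: by stage
    lesion_count_range: Tuple[int, int] = (1, 60)
    lesion_radius_range: Tuple[float, float] = (1.2, 3.5)
    noise_sd: Optional[float] = None  # default: by scanner
    seed: int = 0

    def resolved_nwmh_range(self) -> Tuple[float, float]:
        if self.target_nwmh_range is not None:
            return self.target_nwmh_range
        try:
            return STAGE_NWMH_RANGES[self.stage]
        except KeyError:
            raise GenerationError(f"unknown clinical stage {self.stage!r}") from None


@dataclass
class RaterSpec:
    """Per-voxel corruption model of one simulated automated rater."""

    sensitivity: float = 0.85
    specificity: float = 0.99
    boundary_jitter: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.sensitivity < 1.0 or not 0.0 < self.specificity < 1.0:
            raise ValueError("sensitivity and specificity must lie in (0, 1)")


def _ellipsoid_mask(shape: Sequence[int], center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def generate_phantom(
    spec: PhantomSpec,
) -> Tuple[VolumeImage, BinaryMask, BinaryMask]:
    """Generate one phantom: (volume, gold lesion mask, ICV mask).

    Deterministic per seed.  The realized nWMH always lands inside the
    target range, or a GenerationError is raised.
    """
    rng = np.random.default_rng(spec.seed)
    E = spec.cube_edge
    lo, hi = spec.resolved_nwmh_range()
    if not 0.0 < lo < hi:
        raise GenerationError(f"invalid nWMH target range ({lo}, {hi})")

    # intracranial ellipsoid: 40-60% of the cube
    frac = rng.uniform(0.42, 0.55)
    base_r = (frac * E**3 * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    ratios = rng.uniform(0.92, 1.08, size=3)
    ratios /= ratios.prod() ** (1.0 / 3.0)
    semi = np.minimum(base_r * ratios, E / 2.0 - 1.0)
    center = np.array([E / 2.0] * 3) + rng.uniform(-1.0, 1.0, size=3)
    icv = _ellipsoid_mask((E, E, E), center, semi)
    n_icv = int(icv.sum())
    icv_frac = n_icv / E**3
    if not 0.35 <= icv_frac <= 0.62:
        raise GenerationError(f"ICV fraction {icv_frac:.2f} outside plausible band")

    # smooth tissue background in [~0.25, ~0.6] inside the head, air outside
    field_ = ndimage.gaussian_filter(rng.normal(size=(E, E, E)), sigma=E / 10.0)
    field_ = (field_ - field_.min()) / (field_.max() - field_.min() + 1e-12)
    vol = np.where(icv, 0.25 + 0.35 * field_, 0.0)

    # lesions: hyperintense blobs, total volume calibrated to the target
    target_pct = rng.uniform(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo))
    target_vox = max(3, int(round(target_pct / 100.0 * n_icv)))
    max_vox = int(np.floor(hi / 100.0 * n_icv))
    interior = np.argwhere(
        _ellipsoid_mask((E, E, E), center, semi * 0.80)
    )
    if interior.size == 0:
        raise GenerationError("brain interior empty; cube too small for lesions")
    gold = np.zeros((E, E, E), dtype=bool)
    n_lesions = 0
    min_count, max_count = spec.lesion_count_range
    while int(gold.sum()) < target_vox and n_lesions < max_count:
        remaining = max_vox - int(gold.sum())
        if remaining < 3:
            break
        r = rng.uniform(*spec.lesion_radius_range)
        # shrink the blob if it could overshoot the upper nWMH bound
        r_cap = (remaining * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        r = min(r, max(1.0, r_cap))
        c = interior[rng.integers(len(interior))]
        axes = np.clip(r * rng.uniform(0.8, 1.25, size=3), 1.0, None)
        blob = _ellipsoid_mask((E, E, E), c, axes) & icv
        if int((gold | blob).sum()) > max_vox:
            continue
        gold |= blob
        n_lesions += 1
    realized = 100.0 * gold.sum() / n_icv
    if not lo <= realized <= hi or n_lesions < min_count:
        raise GenerationError(
            f"could not realize nWMH in [{lo}, {hi}]% "
            f"(got {realized:.3f}% with {n_lesions} lesions) for cube edge {E}"
        )

    # lesion intensity: above the in-brain background's 98th percentile
    bg_p98 = np.percentile(vol[icv], 98)
    lesion_core = bg_p98 + 0.25
    vol[gold] = lesion_core + 0.03 * ndimage.gaussian_filter(
        rng.normal(size=(E, E, E)), sigma=1.0
    )[gold]

    gain, offset, scanner_noise = SCANNER_CONTRAST.get(
        spec.scanner_label, SCANNER_CONTRAST["A"]
    )
    noise_sd = spec.noise_sd if spec.noise_sd is not None else scanner_noise
    vol = gain * vol
    vol[icv] += offset
    vol[icv] += rng.normal(0.0, noise_sd, size=n_icv)
    vol = np.clip(vol, 0.0, None)

    volume = VolumeImage(
        data=vol, spacing=(1.0, 1.0, 1.0), scanner_label=spec.scanner_label
    )
    return (
        volume,
        BinaryMask(data=gold, role="gold"),
        BinaryMask(data=icv, role="icv"),
    )


def simulate_rater(
    gold: BinaryMask, spec: RaterSpec, icv: Optional[BinaryMask] = None
) -> BinaryMask:
    """Corrupt a gold mask into one automated-rater ("bronze") mask.

    True voxels survive with probability ``sensitivity``; False voxels flip
    with probability ``1 - specificity``, restricted to the intracranial
    region when an ICV mask is given.  ``boundary_jitter`` passes of random
    boundary voxel flips (both directions, small probability) then roughen
    the lesion outlines, emulating the segmentation-boundary disagreement of
    real tools without systematically shifting lesion volume.
    """
    g = gold.data
    if not g.any():
        raise DegenerateInputError("gold mask is empty; nothing for a rater to see")
    rng = np.random.default_rng(spec.seed)
    head = icv.data if icv is not None else np.ones_like(g)
    # systematic boundary delineation error first (on the clean support),
    # then stochastic per-voxel detection error
    base = g.copy()
    struct = ndimage.generate_binary_structure(3, 1)
    for _ in range(spec.boundary_jitter):
        rim_out = ndimage.binary_dilation(base, struct) & ~base & head
        rim_in = base & ~ndimage.binary_erosion(base, struct, border_value=0)
        base |= rim_out & (rng.random(g.shape) < 0.05)
        base &= ~(rim_in & (rng.random(g.shape) < 0.05))
    out = base & (rng.random(g.shape) < spec.sensitivity)
    fp_region = head & ~base
    out |= fp_region & (rng.random(g.shape) < (1.0 - spec.specificity))
    return BinaryMask(data=out, role="bronze", subject_id=gold.subject_id)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, mix: Dict[str, float]) -> Dict[str, int]:
    keys = sorted(mix)
    total = sum(mix[k] for k in keys)
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"mix proportions must sum to 1, got {total}")
    raw = {k: n * mix[k] / total for k in keys}
    counts = {k: int(np.floor(raw[k])) for k in keys}
    rem = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: raw[k] - counts[k], reverse=True)[:rem]:
        counts[k] += 1
    return counts


def _draw_age(stage: str, rng: np.random.Generator) -> float:
    if stage == "CN":
        # younger and older cognitively-normal modes
        if rng.random() < 0.5:
            return float(np.clip(rng.normal(31.6, 4.4), 20.0, 40.0))
        return float(np.clip(rng.normal(70.0, 8.0), 55.0, 90.0))
    return float(rng.uniform(65.0, 85.0))


@dataclass
class Cohort:
    """In-memory synthetic cohort plus generation provenance."""

    subjects: List[SubjectRecord]
    cube_edge: int
    rater_specs: List[Tuple[float, float, int]]
    master_seed: int

    def __len__(self) -> int:
        return len(self.subjects)

    def annotated(self) -> List[SubjectRecord]:
        return [s for s in self.subjects if s.annotated]

    def unannotated(self) -> List[SubjectRecord]:
        return [s for s in self.subjects if not s.annotated]

    def save(self, out_dir) -> Path:
        """Write NIfTI volumes/masks plus a JSON manifest; returns the
        manifest path.  Layout: <out>/<subject_id>/{flair,gold,icv,bronze_k}.nii.gz
        (gold masks of un-annotated subjects are still written — they serve
        oracle evaluation, never training)."""
        from .io_prep import save_mask, save_volume

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "cube_edge": self.cube_edge,
            "master_seed": self.master_seed,
            "rater_specs": [list(r) for r in self.rater_specs],
            "subjects": [],
        }
        for s in self.subjects:
            sdir = out / s.subject_id
            sdir.mkdir(exist_ok=True)
            paths = {
                "volume": str(sdir / "flair.nii.gz"),
                "gold": str(sdir / "gold.nii.gz"),
                "icv": str(sdir / "icv.nii.gz"),
                "bronze": [
                    str(sdir / f"bronze_{k}.nii.gz") for k in range(len(s.bronze))
                ],
            }
            save_volume(s.volume, paths["volume"])
            save_mask(s.gold, paths["gold"])
            save_mask(s.icv, paths["icv"])
            for bp, bm in zip(paths["bronze"], s.bronze):
                save_mask(bm, bp)
            s.paths = paths
            manifest["subjects"].append(
                {
                    "subject_id": s.subject_id,
                    "stage": s.stage,
                    "scanner": s.scanner_label,
                    "age": s.age,
                    "sex": s.sex,
                    "annotated": s.annotated,
                    **paths,
                }
            )
        mpath = out / "cohort.json"
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=1)
        return mpath


def load_cohort(manifest_path) -> Cohort:
    """Read a cohort manifest written by :meth:`Cohort.save`."""
    from .io_prep import load_mask, load_volume

    with open(manifest_path) as fh:
        manifest = json.load(fh)
    subjects = []
    for rec in manifest["subjects"]:
        sid = rec["subject_id"]
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                stage=rec["stage"],
                scanner_label=rec["scanner"],
                age=rec["age"],
                sex=rec["sex"],
                annotated=rec["annotated"],
                volume=load_volume(rec["volume"], sid, rec["scanner"]),
                gold=load_mask(rec["gold"], "gold", sid),
                icv=load_mask(rec["icv"], "icv", sid),
                bronze=[load_mask(p, "bronze", sid) for p in rec["bronze"]],
                paths=rec,
            )
        )
    return Cohort(
        subjects=subjects,
        cube_edge=manifest["cube_edge"],
        rater_specs=[tuple(r) for r in manifest["rater_specs"]],
        master_seed=manifest["master_seed"],
    )


def generate_cohort(
    n: int,
    stage_mix: Optional[Dict[str, float]] = None,
    scanner_mix: Optional[Dict[str, float]] = None,
    rater_specs: Optional[Sequence[Tuple[float, float, int]]] = None,
    master_seed: int = 0,
    cube_edge: int = 64,
    unannotated_fraction: float = DEFAULT_UNANNOTATED_FRACTION,
) -> Cohort:
    """Generate a full cohort: one volume, gold mask, ICV mask and three
    bronze rater masks per subject, with stage/scanner/demographic labels.

    A fraction of subjects (default 53%, the un-annotated majority of a
    mixed-annotation study) is flagged ``annotated=False``: their gold masks
    are withheld from training and serve only oracle evaluation.
    """
    if n < 10:
        raise ValueError(f"cohort size must be >= 10, got {n}")
    stage_mix = stage_mix or DEFAULT_STAGE_MIX
    scanner_mix = scanner_mix or DEFAULT_SCANNER_MIX
    rater_params = list(rater_specs or DEFAULT_RATER_PARAMS)
    if len(rater_params) < 2:
        raise ValueError("need >= 2 rater specs for consensus fusion")

    stage_counts = _largest_remainder(n, stage_mix)
    scanner_counts = _largest_remainder(n, scanner_mix)
    stages = [s for s in sorted(stage_counts) for _ in range(stage_counts[s])]
    scanners = [s for s in sorted(scanner_counts) for _ in range(scanner_counts[s])]

    ss = np.random.SeedSequence(master_seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    rng.shuffle(stages)
    rng.shuffle(scanners)
    n_unann = int(round(unannotated_fraction * n))
    unann_idx = set(rng.choice(n, size=n_unann, replace=False).tolist())

    subject_seeds = ss.spawn(n)
    subjects: List[SubjectRecord] = []
    for i in range(n):
        sid = f"sub{i:03d}"
        child = subject_seeds[i]
        phantom_seed, *rater_seeds = child.spawn(1 + len(rater_params))
        srng = np.random.default_rng(child)
        stage, scanner = stages[i], scanners[i]
        spec = PhantomSpec(
            cube_edge=cube_edge,
            stage=stage,
            scanner_label=scanner,
            seed=phantom_seed,
        )
        vol, gold, icv = generate_phantom(spec)
        vol.subject_id = gold.subject_id = icv.subject_id = sid
        bronze = [
            simulate_rater(
                gold,
                RaterSpec(
                    sensitivity=p, specificity=q, boundary_jitter=j, seed=rseed
                ),
                icv=icv,
            )
            for (p, q, j), rseed in zip(rater_params, rater_seeds)
        ]
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                stage=stage,
                scanner_label=scanner,
                age=_draw_age(stage, srng),
                sex="M" if srng.random() < 0.5 else "F",
                annotated=i not in unann_idx,
                volume=vol,
                gold=gold,
                icv=icv,
                bronze=bronze,
            )
        )
    return Cohort(
        subjects=subjects,
        cube_edge=cube_edge,
        rater_specs=[tuple(r) for r in rater_params],
        master_seed=master_seed,
    )


REFERENCE_BENCHMARK_N = 40
REFERENCE_BENCHMARK_CUBE = 64
REFERENCE_BENCHMARK_VERSION = 1


def reference_benchmark(seed: int = 7):
    """Canonical desk-scale benchmark: a 40-subject, 64-cube cohort and the
    matched training configuration (16-voxel patches, width-shrunk model).

    Regeneration with the same seed is bit-identical; the version constant
    changes whenever the generating recipe does, so stored results remain
    comparable.
    """
    from .pipeline import TrainConfig

    cohort = generate_cohort(
        n=REFERENCE_BENCHMARK_N,
        master_seed=seed,
        cube_edge=REFERENCE_BENCHMARK_CUBE,
    )
    cfg = TrainConfig.desk_scale(seed=seed)
    return cohort, cfg
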