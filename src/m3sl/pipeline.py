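"""Staged training curriculum: bronze -> silver -> gold.

The curriculum trains the same U-Net three times on progressively cleaner
label tiers, freezing more of the encoder at each hand-off so early, general
feature extractors learned from the large noisy tier are preserved while
later layers specialize:

1. **bronze** — train from scratch on automated-tool masks of the
   un-annotated majority (80/20 train/val, no test set);
2. **silver** — freeze the first 5 encoder conv layers, retrain on the
   STAPLE consensus masks of the same subjects (80/20, stratified by
   scanner so every protocol is represented in both splits);
3. **gold** — freeze the first 10 encoder conv layers, fine-tune on the
   expert-annotated minority under 5-fold cross-validation with a per-fold
   70/10/20 train/val/test division; the five fold test sets are disjoint,
   tile the annotated cohort, and their predictions are concatenated into a
   full-cohort metric report.

Each anatomical orientation (axial, sagittal, coronal) trains its own 2D
network on the slices of lesion-containing patches; at inference the three
probability volumes are averaged and dichotomized at 0.5 (2.5D pooling).
The per-epoch checkpoint with the highest validation IoU is kept.

A gold-only baseline (random init, no freezing, same gold-stage protocol)
is the comparator.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import PipelineConfigError, SplitError
from .io_prep import (
    filter_lesion_patches,
    normalize_dialect,
    orientation_slices,
    pad_mask_to_cube,
    pad_to_cube,
    patchify,
    reconstruct,
    restack,
)
from .losses import combined_loss, combined_loss_grad
from .metrics import MetricReport, evaluate_pair
from .nn import Adam, FreezePlan, ModelSpec, UNet2D, apply_freeze, build_unet
from .staple import binarize_consensus, staple
from .types import ORIENTATION_AXES, BinaryMask, PatchSet, SubjectRecord, VolumeImage

ORIENTATIONS = ("axial", "sagittal", "coronal")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults are the full-scale values (600 epochs, lr 5e-4, focal
    alpha 0.25 / gamma 2.0, 256-cubes with 64-patches); ``desk_scale``
    returns the shrunk configuration used for CPU-scale experiments.
    """

    max_epochs: int = 600
    initial_lr: float = 5e-4
    dice_beta: float = 1.0
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    batch_size: int = 32
    seed: int = 0
    cube_edge: int = 256
    patch_edge: int = 64
    input_edge: int = 64
    width_multiplier: float = 1.0
    stage: str = "gold"
    freeze_silver: int = 5
    freeze_gold: int = 10
    threshold: float = 0.5
    pool_mode: str = "mean"  # "mean" | "vote"
    folds: int = 5
    max_steps_per_epoch: Optional[int] = None
    max_val_slices: Optional[int] = None  # subsample validation for speed
    epochs_by_stage: Optional[Dict[str, int]] = None

    def __post_init__(self):
        if self.max_epochs < 1 or self.initial_lr <= 0 or self.batch_size < 1:
            raise ValueError("max_epochs, initial_lr, batch_size must be positive")
        if not 0.0 < self.focal_alpha < 1.0:
            raise ValueError(f"focal_alpha must lie in (0,1), got {self.focal_alpha}")
        if self.dice_beta <= 0 or self.focal_gamma < 0:
            raise ValueError("dice_beta must be > 0 and focal_gamma >= 0")

    def epochs_for(self, stage: str) -> int:
        if self.epochs_by_stage and stage in self.epochs_by_stage:
            return self.epochs_by_stage[stage]
        return self.max_epochs

    def model_spec(self, seed: int) -> ModelSpec:
        return ModelSpec(
            input_edge=self.input_edge,
            width_multiplier=self.width_multiplier,
            seed=seed,
        )

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "TrainConfig":
        """CPU-scale configuration: 64-cubes, 16-patches, 1/16-width model,
        a handful of epochs per stage with a step cap per epoch."""
        return cls(
            max_epochs=4,
            initial_lr=5e-3,  # the 1/16-width net trains stably faster
            seed=seed,
            cube_edge=64,
            patch_edge=16,
            input_edge=16,
            width_multiplier=1.0 / 16.0,
            batch_size=64,
            max_steps_per_epoch=30,
            max_val_slices=512,
            epochs_by_stage={"bronze": 4, "silver": 3, "gold": 3},
        )


@dataclass
class SplitPlan:
    """Stage-specific data split description."""

    stage: str  # bronze | silver | gold
    fractions: Tuple[float, ...] = ()
    stratify_on: Optional[str] = None
    folds: int = 5

    def __post_init__(self):
        if not self.fractions:
            self.fractions = {
                "bronze": (0.8, 0.2, 0.0),
                "silver": (0.8, 0.2, 0.0),
                "gold": (0.7, 0.1, 0.2),
            }[self.stage]
        if not np.isclose(sum(self.fractions), 1.0):
            raise SplitError(f"fractions must sum to 1, got {self.fractions}")
        if self.stage in ("bronze", "silver") and self.fractions[2] != 0.0:
            raise SplitError(f"{self.stage} stage takes no test set")
        if self.stage == "gold" and self.folds < 2:
            raise SplitError("gold stage needs >= 2 CV folds")
        if self.stage == "silver" and self.stratify_on is None:
            self.stratify_on = "scanner_label"


def _ids(subjects: Sequence[SubjectRecord]) -> List[str]:
    return [s.subject_id for s in subjects]


def make_split(
    subjects: Sequence[SubjectRecord], plan: SplitPlan, seed: int = 0
):
    """Deterministic split assignments for one curriculum stage.

    bronze -> {"train": ids, "val": ids}
    silver -> same, stratified so each stratum's train share is within one
              subject of the requested fraction
    gold   -> list of folds [{"train","val","test"}]; the test partitions
              are disjoint and tile the cohort exactly once
    """
    rng = np.random.default_rng(seed)
    ids = sorted(_ids(subjects))
    if len(set(ids)) != len(ids):
        raise SplitError("duplicate subject ids")
    by_id = {s.subject_id: s for s in subjects}

    if plan.stage in ("bronze", "silver"):
        strata: Dict[str, List[str]]
        if plan.stratify_on:
            strata = {}
            for sid in ids:
                key = str(getattr(by_id[sid], plan.stratify_on))
                strata.setdefault(key, []).append(sid)
        else:
            strata = {"all": list(ids)}
        if len(ids) < 2:
            raise SplitError(f"{len(ids)} subject(s) cannot split train/val")
        train, val = [], []
        for key in sorted(strata):
            members = strata[key]
            perm = list(rng.permutation(members))
            # train share within one subject of the requested fraction;
            # singleton strata go to train
            n_tr = int(round(plan.fractions[0] * len(members)))
            n_tr = min(max(n_tr, 1), len(members))
            train.extend(perm[:n_tr])
            val.extend(perm[n_tr:])
        if not val:  # guarantee a non-empty validation set overall
            big = max(strata.values(), key=len)
            moved = sorted(set(big) & set(train))[-1]
            train.remove(moved)
            val.append(moved)
        return {"train": sorted(train), "val": sorted(val)}

    if plan.stage == "gold":
        if plan.stratify_on:
            counts: Dict[str, int] = {}
            for sid in ids:
                key = str(getattr(by_id[sid], plan.stratify_on))
                counts[key] = counts.get(key, 0) + 1
            small = [k for k, c in counts.items() if c < plan.folds]
            if small:
                raise SplitError(
                    f"strata {small} smaller than fold count {plan.folds}"
                )
        if len(ids) < plan.folds * 2:
            raise SplitError(
                f"{len(ids)} subjects cannot support {plan.folds}-fold CV"
            )
        perm = list(rng.permutation(ids))
        test_parts = [list(part) for part in np.array_split(perm, plan.folds)]
        folds = []
        for k in range(plan.folds):
            test = test_parts[k]
            rest = [sid for sid in perm if sid not in test]
            # 70/10 of the whole = 7/8 vs 1/8 of the non-test remainder
            n_val = max(1, int(round(len(ids) * plan.fractions[1])))
            val = rest[:n_val]
            train = rest[n_val:]
            folds.append(
                {"train": sorted(train), "val": sorted(val), "test": sorted(test)}
            )
        covered = sorted(sid for f in folds for sid in f["test"])
        assert covered == ids, "CV test partitions must tile the cohort"
        return folds

    raise SplitError(f"unknown stage {plan.stage!r}")


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def _prepared_volume(subject: SubjectRecord, cfg: TrainConfig) -> np.ndarray:
    from .synthetic import FAT_SUPPRESSED_SCANNERS

    vol = subject.volume
    if vol is None:
        raise PipelineConfigError(f"{subject.subject_id}: no volume attached")
    if not vol.normalized:
        dialect = (
            "fat_suppressed"
            if vol.scanner_label in FAT_SUPPRESSED_SCANNERS
            else "default"
        )
        vol = normalize_dialect(vol, dialect)
    return pad_to_cube(vol, cfg.cube_edge).data


def _stage_mask(subject: SubjectRecord, tier: str) -> List[BinaryMask]:
    """Training mask(s) of the requested tier for one subject.

    The bronze tier contributes every automated-rater mask as its own
    training target; silver and gold contribute one mask each.
    """
    if tier == "bronze":
        if not subject.bronze:
            raise PipelineConfigError(f"{subject.subject_id}: no bronze masks")
        return list(subject.bronze)
    if tier == "silver":
        if subject.silver is None:
            raise PipelineConfigError(f"{subject.subject_id}: silver mask missing")
        return [subject.silver]
    if tier == "gold":
        if subject.gold is None:
            raise PipelineConfigError(f"{subject.subject_id}: gold mask missing")
        return [subject.gold]
    raise PipelineConfigError(f"unknown mask tier {tier!r}")


def build_slice_dataset(
    subjects: Sequence[SubjectRecord],
    tier: str,
    cfg: TrainConfig,
    orientation: str,
) -> Tuple[np.ndarray, np.ndarray]:
    """Slice-level training arrays (X, Y) for one orientation.

    Volumes are normalized (scanner dialect), padded to the cube edge and
    tiled; only lesion-containing patches of the tier's mask survive; each
    surviving patch contributes its ``patch_edge`` slices perpendicular to
    the orientation axis.
    """
    xs, ys = [], []
    for s in subjects:
        vol = _prepared_volume(s, cfg)
        vol_patches = patchify(vol, cfg.patch_edge)
        for mask in _stage_mask(s, tier):
            m = pad_mask_to_cube(mask, cfg.cube_edge)
            mask_patches = patchify(m.data, cfg.patch_edge)
            fv, fm = filter_lesion_patches(vol_patches, mask_patches)
            for vp, mp in zip(fv.patches, fm.patches):
                xs.append(orientation_slices(vp, orientation))
                ys.append(orientation_slices(mp, orientation))
    if not xs:
        raise PipelineConfigError(
            f"empty {tier} training set: no lesion-containing patches"
        )
    return (
        np.concatenate(xs, axis=0).astype(np.float64),
        np.concatenate(ys, axis=0).astype(np.float64),
    )


# ---------------------------------------------------------------------------
# Stage training
# ---------------------------------------------------------------------------

@dataclass
class StageArtifacts:
    """Outcome of one curriculum stage: per-orientation best models plus
    selection bookkeeping."""

    stage: str
    models: Dict[str, UNet2D]
    best_epoch: Dict[str, int]
    history: Dict[str, List[float]]  # per-epoch validation IoU
    split: object  # the assignments this stage trained under


def _val_iou(model: UNet2D, x: np.ndarray, y: np.ndarray, threshold: float) -> float:
    prob = model.predict(x)
    pred = prob >= threshold
    gt = y >= 0.5
    tp = int(np.count_nonzero(pred & gt))
    den = tp + int(np.count_nonzero(pred & ~gt)) + int(np.count_nonzero(~pred & gt))
    return 1.0 if den == 0 else tp / den


def train_orientation(
    model: UNet2D,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig,
    epochs: int,
    rng: np.random.Generator,
) -> Tuple[UNet2D, int, List[float]]:
    """Adam training with best-validation-IoU checkpointing.

    Returns the model restored to its best epoch, the best epoch index
    (1-based, first occurrence of the maximum), and the IoU history.
    """
    opt = Adam(model.parameters(), lr=cfg.initial_lr)
    history: List[float] = []
    best_state, best_iou, best_epoch = model.state_dict(), -1.0, 0
    n = x_train.shape[0]
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        steps = 0
        for start in range(0, n, cfg.batch_size):
            if cfg.max_steps_per_epoch and steps >= cfg.max_steps_per_epoch:
                break
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            prob = model.forward(xb)
            dprob = combined_loss_grad(
                prob, yb, cfg.dice_beta, cfg.focal_alpha, cfg.focal_gamma
            )
            opt.zero_grad()
            model.backward(dprob)
            opt.step()
            steps += 1
        iou = _val_iou(model, x_val, y_val, cfg.threshold)
        history.append(iou)
        if iou > best_iou:
            best_iou, best_epoch, best_state = iou, epoch, model.state_dict()
    model.load_state_dict(best_state)
    return model, best_epoch, history


def train_stage(
    models: Dict[str, UNet2D],
    subjects: Sequence[SubjectRecord],
    tier: str,
    split: Dict[str, List[str]],
    cfg: TrainConfig,
    freeze_k: int = 0,
) -> StageArtifacts:
    """Train all three orientation models on one label tier.

    The freeze plan is applied before optimization; each orientation trains
    independently on its own slice dataset and keeps its best-IoU epoch.
    """
    by_id = {s.subject_id: s for s in subjects}
    train_subj = [by_id[i] for i in split["train"]]
    val_subj = [by_id[i] for i in split["val"]]
    epochs = cfg.epochs_for(tier)
    best_epoch: Dict[str, int] = {}
    history: Dict[str, List[float]] = {}
    for oi, orientation in enumerate(ORIENTATIONS):
        model = models[orientation]
        apply_freeze(model, FreezePlan(k=freeze_k))
        model.stage_history.append(tier)
        x_tr, y_tr = build_slice_dataset(train_subj, tier, cfg, orientation)
        x_va, y_va = build_slice_dataset(val_subj, tier, cfg, orientation)
        tier_tag = {"bronze": 1, "silver": 2, "gold": 3}[tier]
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, oi, tier_tag]))
        if cfg.max_val_slices and x_va.shape[0] > cfg.max_val_slices:
            # fixed random subsample: an unbiased, cheaper IoU estimate
            keep = rng.choice(x_va.shape[0], size=cfg.max_val_slices, replace=False)
            x_va, y_va = x_va[keep], y_va[keep]
        _, be, hist = train_orientation(
            model, x_tr, y_tr, x_va, y_va, cfg, epochs, rng
        )
        best_epoch[orientation] = be
        history[orientation] = hist
    return StageArtifacts(
        stage=tier, models=models, best_epoch=best_epoch, history=history, split=split
    )


# ---------------------------------------------------------------------------
# Prediction and 2.5D pooling
# ---------------------------------------------------------------------------

def pool_2p5d(
    prob_axial: np.ndarray,
    prob_sagittal: np.ndarray,
    prob_coronal: np.ndarray,
    threshold: float = 0.5,
    mode: str = "mean",
) -> BinaryMask:
    """Fuse the three orientation probability volumes into one mask.

    ``mean``: voxel-wise average of the three, dichotomized at ``threshold``
    (inclusive).  ``vote``: each volume dichotomized first, then majority.
    Permutation-invariant in its three inputs.
    """
    vols = [np.asarray(v) for v in (prob_axial, prob_sagittal, prob_coronal)]
    if not (vols[0].shape == vols[1].shape == vols[2].shape):
        from .errors import AlignmentError

        raise AlignmentError(
            f"orientation volumes disagree: {[v.shape for v in vols]}"
        )
    if mode == "mean":
        fused = (vols[0] + vols[1] + vols[2]) / 3.0 >= threshold
    elif mode == "vote":
        fused = sum((v >= threshold).astype(int) for v in vols) >= 2
    else:
        raise ValueError(f"unknown pooling mode {mode!r}")
    return BinaryMask(data=fused, role="predicted")


def predict_subject(
    models: Dict[str, UNet2D],
    subject: SubjectRecord,
    cfg: TrainConfig,
    filter_tier: str = "gold",
) -> Tuple[BinaryMask, Dict[str, np.ndarray]]:
    """2.5D prediction for one subject.

    Only the lesion-containing patches of the ``filter_tier`` mask are
    predicted (the class-imbalance protocol applies to testing as well);
    filtered-out patches reconstruct as background.  Returns the pooled
    binary mask and the per-orientation probability volumes.
    """
    vol = _prepared_volume(subject, cfg)
    vol_patches = patchify(vol, cfg.patch_edge)
    mask = _stage_mask(subject, filter_tier)[0]
    mask_patches = patchify(pad_mask_to_cube(mask, cfg.cube_edge).data, cfg.patch_edge)
    fv, _ = filter_lesion_patches(vol_patches, mask_patches)
    prob_vols: Dict[str, np.ndarray] = {}
    e = cfg.patch_edge
    for orientation in ORIENTATIONS:
        if len(fv) == 0:
            prob_vols[orientation] = np.zeros((cfg.cube_edge,) * 3)
            continue
        stacks = [orientation_slices(p, orientation) for p in fv.patches]
        flat = np.concatenate(stacks, axis=0)
        prob = models[orientation].predict(flat)
        patches = [
            restack(prob[i * e : (i + 1) * e], orientation) for i in range(len(fv))
        ]
        prob_vols[orientation] = reconstruct(
            PatchSet(
                patches=patches,
                origins=fv.origins,
                edge=e,
                parent_shape=fv.parent_shape,
            )
        )
    fused = pool_2p5d(
        prob_vols["axial"],
        prob_vols["sagittal"],
        prob_vols["coronal"],
        threshold=cfg.threshold,
        mode=cfg.pool_mode,
    )
    fused.subject_id = subject.subject_id
    return fused, prob_vols


def _evaluate_prediction(
    pred: BinaryMask, subject: SubjectRecord, cfg: TrainConfig, variant: str
) -> MetricReport:
    gold = pad_mask_to_cube(subject.gold, cfg.cube_edge)
    icv = pad_mask_to_cube(subject.icv, cfg.cube_edge) if subject.icv else None
    return evaluate_pair(
        pred,
        gold,
        icv=icv,
        spacing=subject.volume.spacing,
        subject_id=subject.subject_id,
        stage=subject.stage,
        scanner=subject.scanner_label,
        variant=variant,
    )


# ---------------------------------------------------------------------------
# Silver mask materialization
# ---------------------------------------------------------------------------

def compute_silver(
    subjects: Sequence[SubjectRecord], threshold: float = 0.5
) -> None:
    """Fill ``subject.silver`` with the STAPLE consensus of the bronze
    masks (in place)."""
    for s in subjects:
        if s.silver is not None:
            continue
        if len(s.bronze) < 2:
            raise PipelineConfigError(
                f"{s.subject_id}: need >= 2 bronze masks for consensus"
            )
        res = staple(s.bronze)
        s.silver = binarize_consensus(res, threshold=threshold, subject_id=s.subject_id)


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Outcome of a full curriculum or baseline run."""

    variant: str
    stage_artifacts: List[StageArtifacts]
    fold_models: List[Dict[str, UNet2D]]
    fold_split: List[Dict[str, List[str]]]
    reports: List[MetricReport]

    def mean_f(self) -> float:
        return float(np.mean([r.f_measure for r in self.reports]))

    def mean_iou(self) -> float:
        return float(np.mean([r.iou for r in self.reports]))


def _fresh_models(cfg: TrainConfig, seed_offset: int = 0) -> Dict[str, UNet2D]:
    return {
        o: build_unet(cfg.model_spec(seed=cfg.seed * 997 + seed_offset * 131 + oi))
        for oi, o in enumerate(ORIENTATIONS)
    }


def _clone_models(models: Dict[str, UNet2D]) -> Dict[str, UNet2D]:
    out = {}
    for o, m in models.items():
        clone = build_unet(m.spec)
        clone.load_state_dict(m.state_dict())
        clone.freeze_history = list(m.freeze_history)
        clone.stage_history = list(m.stage_history)
        if clone.freeze_history:
            from .nn.unet import _set_freeze_flags

            _set_freeze_flags(clone, clone.freeze_history[-1])
        out[o] = clone
    return out


def _gold_cv(
    init_models: Optional[Dict[str, UNet2D]],
    gold_subjects: Sequence[SubjectRecord],
    cfg: TrainConfig,
    freeze_k: int,
    variant: str,
) -> Tuple[List[Dict[str, UNet2D]], List[Dict[str, List[str]]], List[MetricReport], List[StageArtifacts]]:
    """Gold-stage 5-fold CV; each fold starts from ``init_models`` (the
    common post-silver checkpoint) or from random init when None."""
    plan = SplitPlan(stage="gold", folds=cfg.folds)
    folds = make_split(gold_subjects, plan, seed=cfg.seed + 11)
    by_id = {s.subject_id: s for s in gold_subjects}
    fold_models, reports, artifacts = [], [], []
    for fi, fold in enumerate(folds):
        if init_models is None:
            models = _fresh_models(cfg, seed_offset=fi + 1)
        else:
            models = _clone_models(init_models)
        art = train_stage(
            models,
            gold_subjects,
            "gold",
            {"train": fold["train"], "val": fold["val"]},
            replace(cfg, seed=cfg.seed + 100 + fi),
            freeze_k=freeze_k,
        )
        artifacts.append(art)
        fold_models.append(models)
        for sid in fold["test"]:
            pred, _ = predict_subject(models, by_id[sid], cfg, filter_tier="gold")
            reports.append(_evaluate_prediction(pred, by_id[sid], cfg, variant))
    return fold_models, folds, reports, artifacts


def run_m3sl(
    bronze_subjects: Optional[Sequence[SubjectRecord]],
    silver_subjects: Optional[Sequence[SubjectRecord]],
    gold_subjects: Sequence[SubjectRecord],
    cfg: TrainConfig,
) -> RunResult:
    """Full three-stage curriculum run.

    With ``bronze_subjects`` and ``silver_subjects`` both None the run
    degenerates exactly to :func:`run_baseline`.  Silver masks are computed
    by STAPLE on demand.
    """
    if not gold_subjects:
        raise PipelineConfigError("gold stage requires annotated subjects")
    if (bronze_subjects is None) != (silver_subjects is None):
        raise PipelineConfigError(
            "bronze and silver stages must be supplied (or skipped) together"
        )
    artifacts: List[StageArtifacts] = []
    if bronze_subjects is None:
        init_models, freeze_k = None, 0
        variant = "baseline"
    else:
        variant = "m3sl"
        models = _fresh_models(cfg)
        bronze_split = make_split(
            bronze_subjects, SplitPlan(stage="bronze"), seed=cfg.seed + 1
        )
        artifacts.append(
            train_stage(models, bronze_subjects, "bronze", bronze_split, cfg, freeze_k=0)
        )
        compute_silver(silver_subjects, threshold=cfg.threshold)
        silver_split = make_split(
            silver_subjects, SplitPlan(stage="silver"), seed=cfg.seed + 2
        )
        artifacts.append(
            train_stage(
                models, silver_subjects, "silver", silver_split, cfg,
                freeze_k=cfg.freeze_silver,
            )
        )
        init_models, freeze_k = models, cfg.freeze_gold
    fold_models, folds, reports, gold_arts = _gold_cv(
        init_models, gold_subjects, cfg, freeze_k, variant
    )
    artifacts.extend(gold_arts)
    return RunResult(
        variant=variant,
        stage_artifacts=artifacts,
        fold_models=fold_models,
        fold_split=folds,
        reports=reports,
    )


def run_baseline(
    gold_subjects: Sequence[SubjectRecord], cfg: TrainConfig
) -> RunResult:
    """Gold-only comparator: random init, no freezing, same CV protocol."""
    return run_m3sl(None, None, gold_subjects, cfg)


def run_reference_benchmark(master_seed: int = 7) -> Dict[str, RunResult]:
    """Curriculum vs baseline on the canonical synthetic benchmark cohort."""
    from .synthetic import reference_benchmark

    cohort, cfg = reference_benchmark(seed=master_seed)
    unann = cohort.unannotated()
    gold = cohort.annotated()
    m3sl_res = run_m3sl(unann, unann, gold, cfg)
    base_res = run_baseline(gold, cfg)
    return {"m3sl": m3sl_res, "baseline": base_res}
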