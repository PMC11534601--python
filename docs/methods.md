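# Methods

This note records the scientific and numerical choices behind the package:
what the models assume, which parameters matter and why their defaults are
what they are, what the synthetic data does and does not emulate, and the
decisions taken where the design was genuinely open.

## 1. Data preparation

Volumes are standardized to a cube (default edge 256; 64 at desk scale) by
appending zero-valued voxels **at the high-index end of each axis**.
Appending (rather than centering) keeps every original voxel's coordinates
unchanged, so masks padded independently remain voxel-aligned with their
volume. Coordinates are 0-based; patch extents are half-open
[origin, origin+edge).

Intensity normalization maps the [lo, hi] percentile range linearly onto
[0, 1] with two dialects: `default` (0–98th; values above the 98th
percentile clip to 1.0) and `fat_suppressed` (0–100th; pure min-max, used
for scanners whose FLAIR contrast behaves as fat-suppressed — scanner
labels C and E in the synthetic cohort). Clipping the bright tail keeps
the invariant *normalized ⇒ values in [0, 1]* while preventing a few
extreme voxels from compressing the tissue contrast range. A constant
volume normalizes to all zeros.

Cubes are tiled into non-overlapping patches (default 64³, i.e. 64 patches
per 256-cube; 16³ at desk scale) and only patches containing at least one
labeled lesion voxel are kept — in training, validation *and* testing.
This is the class-imbalance control for a task whose true-negative
fraction is ≈ 0.98; its corollary is that reconstruction of a filtered
prediction fills the discarded tiles with background.

## 2. STAPLE consensus

`staple()` implements the standard EM estimator of a consensus
segmentation and per-rater (sensitivity p, specificity q) performance
parameters; the contract is stated in the module docstring. Choices:

- **Prior π** (fixed across iterations): default = the **majority-vote
  foreground fraction** of the input masks. The more obvious default —
  the mean per-rater foreground fraction — is biased upward by rater
  false positives (each rater's FPs are its own, so their union inflates
  apparent prevalence), which measurably deflates the recovered
  sensitivities at low prevalence; majority-vote coincidences on the
  background are rare, so that fraction tracks true prevalence. Both are
  overridable. For cross-checks against ITK-convention implementations,
  pass the mean-foreground prior explicitly.
- **Initialization** p_j = q_j = 0.99 (symmetric, rater-trusting);
  **clamp** ε = 1e-5 on p, q; **tolerance** 1e-6 on the largest parameter
  change; **max 100 iterations**. The observed-data log-likelihood is
  recorded per iteration and is non-decreasing (EM guarantee; asserted in
  tests to 1e-7).
- **Bounding box**: the per-voxel E-step runs only inside the bounding box
  of the union foreground (+1 voxel margin); all-background voxels share
  one closed-form posterior and enter the M-step sums analytically. The
  result is exactly the dense computation (tested to 1e-12).
- **Binarization** at threshold 0.5, inclusive (posterior exactly 0.5 maps
  to foreground), matching the network's output dichotomization.

## 3. Network

A 2D U-Net whose encoder follows the VGG16 convolutional pattern:
blocks of (2, 2, 3, 3, 3) 3×3 same-padding convolutions at widths
(64, 128, 256, 512, 512) — 13 encoder conv layers — with 2×2 max pooling
between blocks, a mirrored decoder (2×2 stride-2 transposed convolutions,
concatenation skips, mirrored conv counts), and a 1×1 convolution plus
sigmoid. Plain conv+ReLU, no batch normalization. `width_multiplier`
scales all widths (1/16 at desk scale ⇒ widths 4–32, ~113k parameters).

- **"First k layers" frozen** counts encoder conv layers from the input:
  k = 5 covers blocks 1–2 plus the first conv of block 3; k = 10 reaches
  the first conv of block 5. Frozen parameters are excluded from optimizer
  updates and remain bitwise identical through any number of steps (the
  core mechanism of the staged curriculum; audited in tests).
- **Implementation**: NumPy, im2col convolutions lowered to BLAS matmuls
  (the input gradient of a stride-1 same convolution is computed as a
  correlation with the spatially flipped kernels — one more matmul instead
  of a scatter loop), hand-written backpropagation verified against finite
  differences at float64 to 1e-4 relative, Adam (β₁ 0.9, β₂ 0.999).
  Default arithmetic is float32; float64 is available for verification.
- **Output bias initialization**: the final conv bias starts at −2 (prior
  ≈ 0.12) rather than 0 (prior 0.5). With ~1–2% foreground, a
  0.5-centered start spends the first training epochs uniformly
  suppressing background; prior-matched bias initialization is the
  standard remedy for rare-foreground objectives and materially shortens
  desk-scale training.
- The 2D networks consume per-orientation slices of the 3D patches: each
  cubic patch contributes its `edge` slices perpendicular to the
  orientation axis; axial, sagittal and coronal models train
  independently.

## 4. Losses

Training minimizes the unweighted sum of:

- **soft Dice loss** = 1 − F_β with soft counts TP = Σ p·g,
  FP = Σ p·(1−g), FN = Σ (1−p)·g and a smoothing term (1e-6) added to
  numerator and denominator. The F_β form is
  (1+β²)TP / ((1+β²)TP + β²FN + FP); β = 1 (the F-measure) by default.
  The denominator simplifies to β²Σg + Σp + s, which the analytic
  gradient uses.
- **binary focal loss**, mean over voxels, with **α on both branches**
  (foreground and background terms both carry α — this follows the
  printed form of the focal criterion used here, rather than the
  α/(1−α) split of the original focal-loss paper); α = 0.25, γ = 2.
  Probabilities at exactly 0 or 1 are clamped to [1e-7, 1−1e-7] with a
  warning.

Reductions: focal is the mean over voxels; the soft Dice is computed over
the whole batch tensor; batches reduce by mean. The hard-count
`dice_score` at β = 1 coincides with the evaluation F-measure exactly
(cross-module identity, tested).

## 5. Training regime and splits

Full-scale defaults: max 600 epochs, Adam at initial learning rate 5e-4,
no schedule, best-validation-IoU checkpointing (first epoch achieving the
maximum wins; no early-stopping patience). Splits: bronze 80/20 train/val
(no test); silver 80/20 stratified by scanner label, each stratum's train
share within one subject of 80% (singleton strata go to train); gold
5-fold CV with per-fold 70/10/20 — test partitions are disjoint,
near-equal, and tile the cohort, so concatenated fold-test predictions
cover every annotated subject exactly once. All splits are deterministic
functions of (subject ids, plan, seed).

Stage hand-offs: freeze 5 before silver, freeze 10 before gold; each gold
fold fine-tunes from the *common* post-silver checkpoint (fresh clone per
fold). The bronze stage uses **all three** automated-rater masks per
subject as separate training targets (the tools' outputs are what that
tier has; discarding two of three would waste most of its signal). The
gold-only baseline is the identical gold-stage protocol from random
initialization with no freezing — `run_m3sl` with the first two stages
skipped reduces to it exactly (tested).

A master seed fans out deterministically to split seeds, per-orientation
initialization seeds, and shuffle streams; identical seeds reproduce
identical metrics bit-for-bit in single-threaded runs.

**Desk-scale configuration** (`TrainConfig.desk_scale()`): 64-cubes,
16-patches, width 1/16, batch 64, at most 30 optimizer steps per epoch,
4/3/3 epochs for bronze/silver/gold, validation IoU estimated on a fixed
512-slice subsample, and learning rate 5e-3. The higher rate reflects the
different optimization regime of a 1/16-width network on 16×16 inputs —
the full-scale default remains 5e-4. These sizes keep a complete
curriculum-plus-baseline benchmark run to a few minutes of one CPU.

## 6. 2.5D pooling

The three orientation probability volumes are averaged voxel-wise and
dichotomized at 0.5 (inclusive). Majority-vote-after-thresholding is
available as `pool_mode="vote"`. Averaging before thresholding preserves
calibrated confidence: two confident orientations outvote one abstention
(mean of 0.9, 0.9, 0.0 = 0.6 ⇒ foreground).

## 7. Metrics

Precision, recall, F-measure and IoU from hard voxel counts; true
negatives never enter (imbalance). Degenerate conventions, chosen so batch
evaluation is total: both masks empty ⇒ all four = 1; exactly one empty ⇒
F = IoU = 0 (and the score whose denominator vanishes is 0).

**HD95** is the 95th percentile (linear interpolation) of the **pooled**
bidirectional surface-distance distribution: boundary voxels are
foreground voxels with a background face-neighbor (6-connectivity);
directed distances come from Euclidean distance transforms of each
boundary set, spacing-aware. The pooled form is symmetric in its
arguments; the max-of-directed-95th-percentiles variant is available via
`pooled=False`. Either mask empty ⇒ NaN sentinel, excluded from group
means but counted in reports. **nWMH** = 100 × lesion volume /
intracranial volume, with the ICV mask supplied as an input.

## 8. Statistics

One-way ANOVA (scipy) with (k−1, N−k) degrees of freedom; identical group
means give F = 0, p = 1. Post-hoc: all pairwise two-sample t-tests with
pooled variance, Holm-Bonferroni step-down corrected as one family,
significance at α = 0.05 (statsmodels supplies the correction). The
type-I error of the ANOVA wrapper is verified by simulation (null
rejection rate within [0.03, 0.07] at α = 0.05 over 1000 draws), and the
Holm step-down is pinned to a hand-worked fixture
((0.01, 0.02, 0.04) → (0.03, 0.04, 0.04)).

## 9. Synthetic cohorts

`generate_phantom` builds, per subject: an ellipsoidal intracranial region
occupying 40–60% of the cube; a smooth tissue background (Gaussian random
field, intensities ≈ 0.25–0.6); hyperintense ellipsoidal blob lesions
placed in the brain interior with total volume calibrated to a
stage-dependent nWMH target — CN 0.01–0.1%, MCI 0.1–0.3%, AD 0.3–1.5% of
ICV, preserving the clinical ordering CN < MCI < AD; lesion intensity sits
above the in-brain background's 98th percentile so lesions stay
hyperintense under every scanner contrast (otherwise the task is
unlearnable at desk scale). Scanner labels A–E apply global gain/offset
and noise-level shifts; C and E additionally use the fat-suppressed
normalization dialect downstream.

`simulate_rater` corrupts the gold mask as an automated tool would:
first `boundary_jitter` passes of stochastic boundary perturbation (rim
voxels flip with probability 0.05 in both directions — a random local
dilation/erosion of magnitude ≤ jitter modeling systematic delineation
error), then per-voxel detection noise (True voxels kept with probability
= sensitivity; False voxels flipped at 1 − specificity, confined to the
intracranial region — automated tools do not hallucinate lesions outside
the head). Jitter precedes the Bernoulli corruption because the reverse
order erodes small desk-scale lesions and drags realized sensitivity well
below its specification; in this order realized rates stay within ±0.01
of spec on large masks (±0.03 with jitter ≤ 2). Default raters:
(0.90, 0.995, jitter 1), (0.75, 0.999, 2), (0.85, 0.990, 1) —
heterogeneous so consensus fusion has reliability differences to exploit.

`generate_cohort` assembles n subjects with stage mix CN/MCI/AD =
0.45/0.35/0.20 and scanner mix A–E = 0.40/0.20/0.15/0.15/0.10 by default
(largest-remainder rounding; an annotated minority dominated by the
reference scanner, as in mixed-cohort studies), flags 53% of subjects as
un-annotated (their gold masks are withheld from training and used only
for oracle evaluation), and draws demographics stage-dependently (CN ages
bimodal — a young ~32 ± 4 mode and an older ~70 ± 8 mode; MCI/AD uniform
65–85; sexes balanced). `reference_benchmark(seed)` pins the canonical
40-subject, 64-cube cohort and the desk-scale `TrainConfig`; regeneration
is bit-identical per seed and the recipe is versioned.

**What the phantoms do not emulate** — and hence what passing tests do
not show about clinical data: no anatomy (no white/gray matter, ventricles
or skull), no partial-volume or bias fields, no k-space or motion
artifacts, no spatial lesion priors (real WMH cluster periventricularly),
and contrast/noise differences between scanners are affine rather than
protocol-specific. Results on the benchmark demonstrate that the
*mechanics* of the curriculum work and that its relative ordering versus
the baseline holds under controlled noise — not clinical-grade accuracy.

## 10. Degenerate inputs and numerical edges

- STAPLE with an all-empty mask union raises (no foreground evidence).
- `dice_score` with all-zero counts raises; the caller chooses the
  convention (evaluation uses the metric-layer conventions above).
- Focal loss probabilities are clamped away from {0, 1} with a warning.
- Max-pool gradient routes ties to the first argmax (deterministic).
- Constant-valued volumes normalize to zero rather than raising.
- Subjects whose stage-tier mask has no lesion voxels contribute no
  patches; an entirely empty training set raises a configuration error.

## 11. Known limitations

- The ImageNet transfer-learning comparator is out of scope by design (no
  pretrained weights); the baseline comparator is the gold-only U-Net.
- Desk-scale accuracy is bounded by the miniature budget (a few epochs at
  width 1/16); the benchmark's purpose is the curriculum-vs-baseline
  contrast, not absolute F.
- The NumPy network trains on CPU only and single-threaded BLAS; it is
  not intended for full-resolution clinical training runs.
- Rigid-body reorientation, bias-field correction, and registration of
  tool masks into FLAIR space are upstream preprocessing, accepted as
  done.
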