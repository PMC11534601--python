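"""VGG16-style 2D U-Net with layer freezing.

The encoder follows the VGG16 convolutional pattern — five blocks of
(2, 2, 3, 3, 3) 3x3 convolutions at widths (64, 128, 256, 512, 512), 13
conv layers in total — with 2x2 max pooling between blocks.  The decoder
mirrors the block structure with transposed-conv upsampling and one
concatenation skip per resolution level; a 1x1 convolution plus sigmoid
yields a per-pixel lesion probability.  ``width_multiplier`` shrinks every
width proportionally so the same topology runs at desk scale on a CPU.

Freezing: the staged curriculum renders the first ``k`` encoder conv layers
(counted from the input, across blocks) untrainable — 5 after the bronze
stage (blocks 1-2 plus the first conv of block 3), 10 after the silver
stage (through the first conv of block 5).  Frozen parameters are excluded
from optimizer updates and remain bitwise identical through training.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ..errors import ArchitectureError, ShapeError
from .core import Adam, Conv2d, ConvTranspose2d, MaxPool2, Param, relu, relu_grad, sigmoid

VGG16_BLOCKS: Tuple[Tuple[int, int], ...] = ((2, 64), (2, 128), (3, 256), (3, 512), (3, 512))


@dataclass
class ModelSpec:
    """Architecture hyperparameters (a pure function of which the parameter
    count and layout are determined)."""

    encoder_blocks: Sequence[Tuple[int, int]] = VGG16_BLOCKS
    input_edge: int = 64
    width_multiplier: float = 1.0
    seed: int = 0
    dtype: str = "float32"  # "float64" for gradient verification
    out_bias: float = -2.0  # prior-matched logit init for rare foreground

    def widths(self) -> List[int]:
        return [max(1, round(c * self.width_multiplier)) for _, c in self.encoder_blocks]

    @property
    def n_encoder_convs(self) -> int:
        return sum(n for n, _ in self.encoder_blocks)

    def to_dict(self) -> dict:
        return {
            "encoder_blocks": [list(b) for b in self.encoder_blocks],
            "input_edge": self.input_edge,
            "width_multiplier": self.width_multiplier,
            "seed": self.seed,
            "dtype": self.dtype,
            "out_bias": self.out_bias,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            encoder_blocks=tuple(tuple(b) for b in d["encoder_blocks"]),
            input_edge=int(d["input_edge"]),
            width_multiplier=float(d["width_multiplier"]),
            seed=int(d["seed"]),
            dtype=d.get("dtype", "float32"),
            out_bias=float(d.get("out_bias", -2.0)),
        )


@dataclass
class FreezePlan:
    """Number of leading encoder conv layers excluded from training."""

    k: int = 0


class UNet2D:
    """Seeded, deterministic U-Net over single-channel 2D slices."""

    def __init__(self, spec: ModelSpec):
        nb = len(spec.encoder_blocks)
        if spec.input_edge % (2 ** (nb - 1)) != 0:
            raise ArchitectureError(
                f"input_edge {spec.input_edge} not divisible by 2^{nb - 1}; "
                "the encoder cannot downsample it"
            )
        self.spec = spec
        self.freeze_history: List[int] = []
        self.stage_history: List[str] = []
        rng = np.random.default_rng(spec.seed)
        widths = spec.widths()
        dt = np.dtype(spec.dtype).type

        # encoder: blocks of convs, pooling between blocks
        self.enc_convs: List[List[Conv2d]] = []
        self.pools: List[MaxPool2] = []
        cin = 1
        for bi, (nconv, _) in enumerate(spec.encoder_blocks):
            block = []
            for ci in range(nconv):
                block.append(Conv2d(cin, widths[bi], f"enc{bi}c{ci}", rng, dtype=dt))
                cin = widths[bi]
            self.enc_convs.append(block)
            if bi < nb - 1:
                self.pools.append(MaxPool2())

        # decoder mirrors blocks nb-2 .. 0
        self.up_convs: List[ConvTranspose2d] = []
        self.dec_convs: List[List[Conv2d]] = []
        cur = widths[-1]
        for bi in range(nb - 2, -1, -1):
            self.up_convs.append(ConvTranspose2d(cur, widths[bi], f"up{bi}", rng, dtype=dt))
            nconv = spec.encoder_blocks[bi][0]
            block = []
            cin = widths[bi] * 2  # concat skip
            for ci in range(nconv):
                block.append(Conv2d(cin, widths[bi], f"dec{bi}c{ci}", rng, dtype=dt))
                cin = widths[bi]
            self.dec_convs.append(block)
            cur = widths[bi]
        self.out_conv = Conv2d(cur, 1, "out", rng, k=1, dtype=dt)
        # start the sigmoid near the foreground prevalence instead of 0.5,
        # so early training is not spent suppressing the background class
        self.out_conv.b.value[:] = spec.out_bias
        self._cache = None

    # -- parameter bookkeeping ------------------------------------------------

    def encoder_conv_layers(self) -> List[Conv2d]:
        """Encoder convs in input-to-depth order (the freeze-count unit)."""
        return [c for block in self.enc_convs for c in block]

    def parameters(self) -> List[Param]:
        ps: List[Param] = []
        for c in self.encoder_conv_layers():
            ps.extend(c.params())
        for u, block in zip(self.up_convs, self.dec_convs):
            ps.extend(u.params())
            for c in block:
                ps.extend(c.params())
        ps.extend(self.out_conv.params())
        return ps

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    # -- forward / backward ---------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, edge, edge) or (N, 1, edge, edge) -> probabilities, same
        spatial shape, strictly inside (0, 1)."""
        squeeze = False
        if x.ndim == 3:
            x = x[:, None]
            squeeze = True
        if x.shape[2] != self.spec.input_edge or x.shape[3] != self.spec.input_edge:
            raise ShapeError(
                f"expected {self.spec.input_edge}^2 slices, got {x.shape[2]}x{x.shape[3]}"
            )
        nb = len(self.enc_convs)
        skips, pre_acts = [], []
        h = np.asarray(x, dtype=np.dtype(self.spec.dtype))
        for bi in range(nb):
            for conv in self.enc_convs[bi]:
                z = conv.forward(h)
                pre_acts.append(z)
                h = relu(z)
            if bi < nb - 1:
                skips.append(h)
                h = self.pools[bi].forward(h)
        dec_pre, concat_splits = [], []
        for li, (up, block) in enumerate(zip(self.up_convs, self.dec_convs)):
            h = up.forward(h)
            skip = skips[-(li + 1)]
            concat_splits.append(skip.shape[1])
            h = np.concatenate([h, skip], axis=1)
            for conv in block:
                z = conv.forward(h)
                dec_pre.append(z)
                h = relu(z)
        logits = self.out_conv.forward(h)
        prob = sigmoid(logits)
        self._cache = (pre_acts, dec_pre, concat_splits, prob, squeeze)
        return prob[:, 0] if squeeze else prob

    def backward(self, dprob: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dprob."""
        pre_acts, dec_pre, concat_splits, prob, squeeze = self._cache
        if dprob.ndim == 3:
            dprob = dprob[:, None]
        # through sigmoid; cast once so float64 loss grads don't upcast the net
        dz = np.asarray(dprob * prob * (1.0 - prob), dtype=prob.dtype)
        dh = self.out_conv.backward(dz)
        pi = len(dec_pre)
        dskips = [None] * len(self.up_convs)
        for li in range(len(self.up_convs) - 1, -1, -1):
            block = self.dec_convs[li]
            for conv in reversed(block):
                pi -= 1
                dh = conv.backward(relu_grad(dec_pre[pi], dh))
            nup = dh.shape[1] - concat_splits[li]
            dup, dskip = dh[:, :nup], dh[:, nup:]
            dskips[li] = dskip
            dh = self.up_convs[li].backward(dup)
        nb = len(self.enc_convs)
        ei = len(pre_acts)
        for bi in range(nb - 1, -1, -1):
            if bi < nb - 1:
                # decoder level li = nb-2-bi consumed this block's skip
                dh = self.pools[bi].backward(dh) + dskips[nb - 2 - bi]
            for conv in reversed(self.enc_convs[bi]):
                ei -= 1
                dh = conv.backward(relu_grad(pre_acts[ei], dh))
        self._cache = None

    def predict(self, slices: np.ndarray, batch: int = 256) -> np.ndarray:
        """Inference on a stack of slices; deterministic for fixed weights."""
        slices = np.asarray(slices, dtype=np.dtype(self.spec.dtype))
        out = np.empty_like(slices)
        for s in range(0, slices.shape[0], batch):
            out[s : s + batch] = self.forward(slices[s : s + batch])
            self._cache = None
        return out

    # -- persistence ----------------------------------------------------------

    def state_dict(self) -> dict:
        return {p.name: p.value.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict) -> None:
        for p in self.parameters():
            p.value[...] = np.asarray(state[p.name], dtype=p.value.dtype)

    def save(self, path) -> None:
        """Write weights (.npz) plus a JSON sidecar with the spec, the
        freeze-plan history and training-stage provenance."""
        path = str(path)
        np.savez(path if path.endswith(".npz") else path + ".npz", **self.state_dict())
        sidecar = {
            "spec": self.spec.to_dict(),
            "freeze_history": self.freeze_history,
            "stage_history": self.stage_history,
        }
        side = (path[: -len(".npz")] if path.endswith(".npz") else path) + ".json"
        with open(side, "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path) -> "UNet2D":
        path = str(path)
        base = path[: -len(".npz")] if path.endswith(".npz") else path
        with open(base + ".json") as fh:
            sidecar = json.load(fh)
        model = cls(ModelSpec.from_dict(sidecar["spec"]))
        model.freeze_history = list(sidecar["freeze_history"])
        model.stage_history = list(sidecar["stage_history"])
        with np.load(base + ".npz") as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
        if model.freeze_history:
            _set_freeze_flags(model, model.freeze_history[-1])
        return model


def build_unet(spec: ModelSpec) -> UNet2D:
    """Construct the network; same spec (incl. seed) => identical weights."""
    return UNet2D(spec)


def _set_freeze_flags(model: UNet2D, k: int) -> None:
    layers = model.encoder_conv_layers()
    if not 0 <= k <= len(layers):
        raise ValueError(
            f"freeze count k={k} outside [0, {len(layers)}] encoder conv layers"
        )
    for i, conv in enumerate(layers):
        for p in conv.params():
            p.trainable = i >= k


def apply_freeze(model: UNet2D, plan: FreezePlan) -> UNet2D:
    """Mark the first ``plan.k`` encoder conv layers untrainable (in place).

    Later layers are (re-)enabled, so applying a smaller plan after a larger
    one unfreezes the difference.
    """
    _set_freeze_flags(model, plan.k)
    model.freeze_history.append(plan.k)
    return model


def predict_slices(model: UNet2D, slices: np.ndarray) -> np.ndarray:
    """Probability maps for a stack of 2D slices (shape-preserving)."""
    slices = np.asarray(slices, dtype=np.float64)
    if slices.ndim != 3:
        raise ShapeError(f"expected (n, h, w) slice stack, got shape {slices.shape}")
    return model.predict(slices)
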