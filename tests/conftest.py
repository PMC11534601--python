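import numpy as np
import pytest

from m3sl.synthetic import PhantomSpec, generate_phantom
from m3sl.types import BinaryMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 48-cube AD phantom shared across tests."""
    return generate_phantom(PhantomSpec(cube_edge=48, stage="AD", seed=42))


def make_block_mask(shape, lo, hi, role="gold"):
    """Axis-aligned cuboid mask helper."""
    m = np.zeros(shape, dtype=bool)
    m[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return BinaryMask(data=m, role=role)


def simulated_raters(truth, specs, seed=0):
    """Corrupt a boolean truth grid with per-voxel (sensitivity, specificity)
    Bernoulli flips — the independent generator used to validate STAPLE."""
    masks = []
    for j, (p, q) in enumerate(specs):
        r = np.random.default_rng(seed * 1000 + j + 1)
        m = np.where(truth, r.random(truth.shape) < p, r.random(truth.shape) < (1 - q))
        masks.append(BinaryMask(data=m.astype(bool), role="bronze"))
    return masks
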