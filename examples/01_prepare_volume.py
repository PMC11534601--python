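"""Data preparation: pad a variable-depth scan to a cube, normalize its
intensities, tile it into patches, and keep only lesion-bearing tiles.

Run:  python examples/01_prepare_volume.py
"""
import numpy as np

from m3sl import (
    filter_lesion_patches,
    normalize_dialect,
    pad_mask_to_cube,
    pad_to_cube,
    patchify,
)
from m3sl.synthetic import PhantomSpec, generate_phantom

# A synthetic "acquisition": 64x64 in-plane, only 40 slices deep — as with
# 2D FLAIR protocols whose slice count varies between scans.
vol, gold, icv = generate_phantom(PhantomSpec(cube_edge=64, stage="AD", seed=5))
thin = vol.with_data(vol.data[:, :, :40])
thin_gold = gold.data[:, :, :40]

padded = pad_to_cube(thin, 64)
print(f"padded {thin.shape} -> {padded.shape}; "
      f"intensity sum preserved: {np.isclose(padded.data.sum(), thin.data.sum())}")

normed = normalize_dialect(padded, "default")  # 0-98th percentile, tail clipped
print(f"normalized range: [{normed.data.min():.3f}, {normed.data.max():.3f}], "
      f"{(normed.data == 1.0).mean():.1%} of voxels clipped at 1.0")

vol_patches = patchify(normed.data, 16)
from m3sl.types import BinaryMask

mask_patches = patchify(
    pad_mask_to_cube(BinaryMask(data=thin_gold), 64).data, 16
)
kept_vol, kept_mask = filter_lesion_patches(vol_patches, mask_patches)
print(f"{len(vol_patches)} tiles of 16^3; {len(kept_vol)} contain lesion voxels "
      "and would enter training — the class-imbalance filter discards the rest.")
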