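"""Patch tiling and gray-tone sampling at Sophie Germain mask positions.

A time-frequency image of size S is tiled into non-overlapping n x n
patches (n must divide S).  Within each patch the gray tones at the cells
where Sophie Germain primes fall on an n x n Ulam spiral are read out, in
ascending prime order.  The per-segment feature vector concatenates these
reads channel-major, then patch row-major, then prime-ascending, giving

    length = channels * (S / n)**2 * sg_count(n)

= 19 * 225 * 15 = 64125 at the reference configuration (19 channels,
225 x 225 image, 15 x 15 patches).  Whole-image mode (n == S) treats the
full image as a single patch with an S x S spiral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timefreq import TFImage
from .ulam_sg import SGMask, sg_count, sg_mask

__all__ = [
    "PatchGrid",
    "SegmentFeatureVector",
    "patchify",
    "extract_patch_features",
    "segment_features",
    "feature_length",
]


@dataclass
class PatchGrid:
    """Row-major list of n x n sub-images tiling one image exactly."""

    patches: list[np.ndarray]
    n: int
    rows_of_patches: int
    cols_of_patches: int


@dataclass
class SegmentFeatureVector:
    """Gray tones (0-255) for one segment, with its label."""

    values: np.ndarray
    label: str
    segment_id: str


def patchify(img: TFImage | np.ndarray, n: int) -> PatchGrid:
    """Tile a square image into non-overlapping n x n patches, row-major."""
    pixels = img.pixels if isinstance(img, TFImage) else np.asarray(img)
    size = pixels.shape[0]
    if pixels.ndim != 2 or pixels.shape[1] != size:
        raise ValueError(f"expected a square image, got shape {pixels.shape}")
    if n < 1 or size % n != 0:
        raise ValueError(
            f"patch size {n} does not divide image size {size} exactly"
        )
    k = size // n
    patches = [
        pixels[i * n : (i + 1) * n, j * n : (j + 1) * n]
        for i in range(k)
        for j in range(k)
    ]
    return PatchGrid(patches=patches, n=n, rows_of_patches=k, cols_of_patches=k)


def extract_patch_features(patch: np.ndarray, mask: SGMask) -> np.ndarray:
    """Gray values at the mask coordinates, in mask (ascending-prime) order."""
    patch = np.asarray(patch)
    if patch.shape != (mask.n, mask.n):
        raise ValueError(
            f"patch shape {patch.shape} does not match mask size {mask.n}"
        )
    rows = [rc[0] for rc in mask.coords]
    cols = [rc[1] for rc in mask.coords]
    return patch[rows, cols]


def feature_length(channels: int, image_size: int, n: int) -> int:
    """channels * (image_size/n)^2 * sg_count(n); validates divisibility."""
    if image_size % n != 0:
        raise ValueError(f"patch size {n} does not divide image size {image_size}")
    return channels * (image_size // n) ** 2 * sg_count(n)


def segment_features(
    seg_images: list[TFImage], n: int, label: str = "", segment_id: str = ""
) -> SegmentFeatureVector:
    """Concatenate masked gray tones over channels and patches.

    Ordering is channel-major (input image order), then patch row-major,
    then ascending prime within each patch — bit-reproducible.
    """
    if not seg_images:
        raise ValueError("segment_features needs at least one channel image")
    sizes = {img.size for img in seg_images}
    if len(sizes) > 1:
        raise ValueError(f"heterogeneous image sizes: {sorted(sizes)}")
    mask = sg_mask(n)
    out = []
    for img in seg_images:
        grid = patchify(img, n)
        for patch in grid.patches:
            out.append(extract_patch_features(patch, mask))
    values = np.concatenate(out) if out else np.empty(0, dtype=np.uint8)
    return SegmentFeatureVector(values=values, label=label, segment_id=segment_id)
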