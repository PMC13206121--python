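"""Tissue segmentation, patch extraction and slide-level quality control.

The segmentation recipe: downsample the RGB slide by an integer factor
(default 32) with exact block averaging, convert to HSV, call foreground
wherever the saturation channel (0-255 scale) strictly exceeds a threshold
(default 15), then apply morphological closing followed by opening with a
7x7 elliptical structuring element, two iterations each. Patches are taken
on a non-overlapping 256x256 grid anchored at pixel (0, 0) at level 0;
partial edge tiles are discarded, and a tile is kept when the foreground
proportion of its aligned 8x8 block in the downsampled mask strictly
exceeds 20%. Slides with fewer than 10 tissue patches are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.measure import block_reduce
from skimage.morphology import ellipse as ellipse_footprint
from skimage.transform import resize as _resize

__all__ = [
    "SegmentationParams",
    "PatchRecord",
    "segment_tissue",
    "extract_patches",
    "qc_slide",
    "standardize_patch",
]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass
class SegmentationParams:
    downsample: int = 32
    sat_threshold: int = 15  # on the 0-255 saturation scale, strict >
    morph_kernel: tuple[int, int] = (7, 7)  # elliptical structuring element
    morph_iterations: int = 2
    patch_size: int = 256  # level-0 pixels, non-overlapping grid
    tissue_fraction_min: float = 0.20  # strict >
    min_patches_per_slide: int = 10
    resize_to: int = 224
    norm_mean: tuple[float, float, float] = IMAGENET_MEAN
    norm_std: tuple[float, float, float] = IMAGENET_STD

    def __post_init__(self):
        if self.patch_size % self.downsample != 0:
            raise ValueError("patch_size must be divisible by downsample")
        if not (0 <= self.sat_threshold <= 255):
            raise ValueError("sat_threshold must be in [0, 255]")
        if not (0.0 <= self.tissue_fraction_min <= 1.0):
            raise ValueError("tissue_fraction_min must be in [0, 1]")

    @property
    def footprint(self) -> np.ndarray:
        ky, kx = self.morph_kernel
        return ellipse_footprint(ky // 2, kx // 2).astype(bool)


class PatchRecord(NamedTuple):
    x: int  # level-0 pixel origin, column
    y: int  # level-0 pixel origin, row
    patch: np.ndarray  # (patch_size, patch_size, 3) uint8
    tissue_fraction: float


def segment_tissue(
    image: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Binary tissue mask at downsampled resolution (H//ds, W//ds)."""
    params = params or SegmentationParams()
    ds = params.downsample
    h, w = image.shape[:2]
    if h < ds or w < ds:
        raise ValueError(f"image {h}x{w} smaller than downsample factor {ds}")
    # trim to an exact multiple so block averaging is unambiguous
    img = image[: (h // ds) * ds, : (w // ds) * ds].astype(np.float64)
    # block mean, then 8-bit quantization at each stage (as in integer
    # image pipelines), so the strict threshold has exact semantics
    small = np.round(block_reduce(img, (ds, ds, 1), func=np.mean))
    sat = np.round(rgb2hsv(small / 255.0)[..., 1] * 255.0)
    mask = sat > params.sat_threshold

    fp = params.footprint
    it = params.morph_iterations
    # closing then opening, each with `it` iterations of its half-operations;
    # erosion treats the outside as foreground (the usual convention, so a
    # fully-tissue image is not eaten from the borders)
    mask = ndimage.binary_erosion(
        ndimage.binary_dilation(mask, structure=fp, iterations=it),
        structure=fp, iterations=it, border_value=1,
    )
    mask = ndimage.binary_dilation(
        ndimage.binary_erosion(mask, structure=fp, iterations=it, border_value=1),
        structure=fp, iterations=it,
    )
    return mask


def extract_patches(
    image: np.ndarray,
    mask: np.ndarray,
    params: SegmentationParams | None = None,
) -> list[PatchRecord]:
    """Tiles on the non-overlapping level-0 grid passing the tissue filter.

    The tissue fraction of a tile is the foreground proportion of its aligned
    (patch_size/downsample)^2 block in the downsampled mask; a tile is kept
    when that fraction strictly exceeds ``tissue_fraction_min``. Partial edge
    tiles are discarded.
    """
    params = params or SegmentationParams()
    ds, ps = params.downsample, params.patch_size
    h, w = image.shape[:2]
    if mask.shape[0] != h // ds or mask.shape[1] != w // ds:
        raise ValueError("mask size does not match image / downsample factor")
    b = ps // ds
    out: list[PatchRecord] = []
    for row in range(h // ps):
        for col in range(w // ps):
            block = mask[row * b : (row + 1) * b, col * b : (col + 1) * b]
            frac = float(block.mean())
            if frac > params.tissue_fraction_min:
                y, x = row * ps, col * ps
                out.append(
                    PatchRecord(x=x, y=y, patch=image[y : y + ps, x : x + ps],
                                tissue_fraction=frac)
                )
    return out


def qc_slide(n_patches: int, params: SegmentationParams | None = None) -> bool:
    """True (keep) iff the slide yields at least ``min_patches_per_slide``."""
    params = params or SegmentationParams()
    if n_patches < 0:
        raise ValueError("n_patches must be non-negative")
    return n_patches >= params.min_patches_per_slide


def standardize_patch(
    patch: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Bilinear resize to resize_to^2 and ImageNet per-channel standardize."""
    params = params or SegmentationParams()
    ps = params.patch_size
    if patch.shape[:2] != (ps, ps):
        raise ValueError(f"expected {ps}x{ps} patch, got {patch.shape[:2]}")
    t = params.resize_to
    x = _resize(
        patch.astype(np.float64), (t, t), order=1,
        preserve_range=True, anti_aliasing=False,
    )
    x = x / 255.0
    mean = np.asarray(params.norm_mean)
    std = np.asarray(params.norm_std)
    return (x - mean) / std
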