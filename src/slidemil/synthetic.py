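"""Synthetic cohort generation for desk-scale MIL experiments.

Emulates the statistical structure of a severely imbalanced epithelial
ovarian cancer WSI cohort: five subtypes (HGSC, EC, CC, LGSC, MC) at
42.5/23.1/18.2/8.0/8.0% prevalence, per-slide patch counts spanning
228-34,412 (median 7,864), and per-slide bags mixing "tumor" patches drawn
around a class-specific centroid with "background" patches drawn around the
origin. The separation knob rho scales the class-centroid radius and plays
the role of feature-extractor quality: rho = 0 carries no class signal at
all, large rho makes bags near-perfectly separable.

Also provides synthetic slide images (elliptical saturated tissue blobs on a
white background, with an exact ground-truth tissue mask) as fixtures for
the preprocessing pipeline, and patch-grid annotation masks of either
polarity (tumor or normal) for the attention-alignment metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
from skimage.color import hsv2rgb
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "SUBTYPES",
    "DEFAULT_PROPORTIONS",
    "CohortConfig",
    "PatchBag",
    "SyntheticSlide",
    "class_centroids",
    "largest_remainder",
    "generate_cohort",
    "generate_slide_image",
    "generate_annotation",
    "write_bag",
    "read_bag",
    "write_cohort",
    "read_cohort",
]

SUBTYPES = ("HGSC", "EC", "CC", "LGSC", "MC")
DEFAULT_PROPORTIONS = (0.425, 0.231, 0.182, 0.080, 0.080)

# fixed seed for the class centroids: every cohort (whatever its seed) shares
# the same class geometry, so models trained on one cohort transfer to another
_CENTROID_SEED = 20240


@dataclass
class CohortConfig:
    """Generative parameters for one synthetic cohort."""

    n_slides: int = 510
    class_proportions: Sequence[float] = DEFAULT_PROPORTIONS
    embed_dim: int = 64
    separation: float = 2.0  # rho: class-centroid radius ("feature quality")
    noise: float = 1.0  # sigma: isotropic patch noise
    tumor_fraction_params: tuple[float, float] = (8.0, 2.0)  # Beta(a, b)
    patch_count_range: tuple[int, int] = (228, 34412)
    patch_count_median: int = 7864
    patch_count_sigma: float = 0.63  # log-normal spread (mean/median ratio 1.22)
    seed: int = 0

    def __post_init__(self):
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape != (5,):
            raise ValueError("class_proportions must have length 5")
        # printed prevalences are rounded (42.5/23.1/18.2/8.0/8.0 sums to
        # 99.8%); accept rounding slack and renormalize to an exact simplex
        if abs(props.sum() - 1.0) > 5e-3:
            raise ValueError(f"class proportions sum to {props.sum()}, not 1")
        if (props < 0).any():
            raise ValueError("class proportions must be non-negative")
        object.__setattr__(self, "class_proportions", tuple(props / props.sum()))
        if self.n_slides < 1 or self.embed_dim < 1:
            raise ValueError("n_slides and embed_dim must be positive")
        if self.separation < 0:
            raise ValueError("separation (rho) must be non-negative")
        if self.noise <= 0:
            raise ValueError("noise (sigma) must be positive")
        lo, hi = self.patch_count_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid patch_count_range")


@dataclass
class PatchBag:
    """One slide's bag of instances."""

    slide_id: str
    features: np.ndarray  # (N, d) float32
    coords: np.ndarray  # (N, 2) int32, (col, row) on the patch grid
    label: int  # 0..4 -> HGSC, EC, CC, LGSC, MC
    tumor_flags: Optional[np.ndarray] = None  # (N,) uint8 ground truth

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int32)
        n = self.features.shape[0]
        if n < 1:
            raise ValueError("bag must contain at least one instance")
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be (N, 2)")
        if (self.coords < 0).any():
            raise ValueError("coords must be non-negative")
        uniq = {tuple(c) for c in self.coords.tolist()}
        if len(uniq) != n:
            raise ValueError("coords must be unique within a bag")
        if not (0 <= self.label <= 4):
            raise ValueError(f"invalid label {self.label}")
        if self.tumor_flags is not None:
            self.tumor_flags = np.asarray(self.tumor_flags, dtype=np.uint8)
            if self.tumor_flags.shape != (n,):
                raise ValueError("tumor_flags must be (N,)")

    @property
    def n_patches(self) -> int:
        return self.features.shape[0]


@dataclass
class SyntheticSlide:
    image: np.ndarray  # (H, W, 3) uint8
    truth_mask: np.ndarray  # (H, W) bool
    annotation_mask: Optional[np.ndarray] = None
    annotation_polarity: str = "tumor"

    def __post_init__(self):
        if self.truth_mask.shape != self.image.shape[:2]:
            raise ValueError("truth_mask must match image size")


def class_centroids(embed_dim: int) -> np.ndarray:
    """Fixed unit-norm centroids for the five subtypes, deterministic in d."""
    rng = np.random.default_rng(_CENTROID_SEED)
    c = rng.standard_normal((len(SUBTYPES), embed_dim))
    return c / np.linalg.norm(c, axis=1, keepdims=True)


def largest_remainder(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Apportion n items to classes by the largest-remainder method.

    Ties in the fractional part are broken toward the lower class index.
    """
    props = np.asarray(proportions, dtype=float)
    quota = n * props
    counts = np.floor(quota).astype(int)
    remainder = n - counts.sum()
    # stable sort on -fraction => ties resolve to the lower index
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def _sample_coords(n: int, rng: np.random.Generator) -> np.ndarray:
    side = int(np.ceil(np.sqrt(n)))
    cells = rng.choice(side * side, size=n, replace=False)
    return np.stack([cells % side, cells // side], axis=1).astype(np.int32)


def generate_cohort(config: CohortConfig) -> tuple[list[PatchBag], pd.DataFrame]:
    """Draw a full synthetic cohort; bitwise reproducible from config.seed."""
    rng = np.random.default_rng(config.seed)
    counts = largest_remainder(config.n_slides, config.class_proportions)
    labels = np.repeat(np.arange(5), counts)
    rng.shuffle(labels)

    centroids = class_centroids(config.embed_dim)
    a, b = config.tumor_fraction_params
    lo, hi = config.patch_count_range
    mu = np.log(config.patch_count_median)

    bags: list[PatchBag] = []
    rows = []
    for i, label in enumerate(labels):
        n = int(np.clip(round(np.exp(rng.normal(mu, config.patch_count_sigma))), lo, hi))
        frac = rng.beta(a, b)
        n_tumor = int(np.clip(round(frac * n), 0, n))
        flags = np.zeros(n, dtype=np.uint8)
        flags[rng.permutation(n)[:n_tumor]] = 1

        feats = rng.normal(0.0, config.noise, size=(n, config.embed_dim))
        feats[flags == 1] += config.separation * centroids[label]
        bag = PatchBag(
            slide_id=f"S{i:04d}",
            features=feats.astype(np.float32),
            coords=_sample_coords(n, rng),
            label=int(label),
            tumor_flags=flags,
        )
        bags.append(bag)
        rows.append(
            {"slide_id": bag.slide_id, "label": int(label),
             "subtype": SUBTYPES[label], "n_patches": n}
        )
    return bags, pd.DataFrame(rows)


def generate_slide_image(
    width: int,
    height: int,
    n_blobs: int,
    blob_saturation: int = 200,
    seed: int = 0,
    blobs: Optional[Sequence[tuple]] = None,
) -> SyntheticSlide:
    """Synthetic slide: saturated elliptical tissue blobs on a white background.

    Parameters
    ----------
    blobs
        Optional explicit geometry, a list of (row, col, r_radius, c_radius,
        rotation) tuples; overrides random placement (n_blobs is then ignored).
        The truth mask marks blob pixels exactly.
    """
    if width < 1 or height < 1:
        raise ValueError("degenerate image size")
    if not (0 <= blob_saturation <= 255):
        raise ValueError("blob_saturation must be in [0, 255]")
    rng = np.random.default_rng(seed)
    image = np.full((height, width, 3), 255, dtype=np.uint8)
    mask = np.zeros((height, width), dtype=bool)

    if blobs is None:
        blobs = []
        for _ in range(n_blobs):
            r = rng.uniform(0.2, 0.8) * height
            c = rng.uniform(0.2, 0.8) * width
            # radii sized so blobs survive 32x downsampling plus morphology
            rr = rng.uniform(0.15, 0.35) * height
            cr = rng.uniform(0.15, 0.35) * width
            rot = rng.uniform(0, np.pi)
            blobs.append((r, c, rr, cr, rot))

    for r, c, rr, cr, rot in blobs:
        yy, xx = draw_ellipse(r, c, rr, cr, shape=mask.shape, rotation=rot)
        hue = rng.uniform(0.0, 1.0)
        sat = rng.uniform(blob_saturation, 255.0) / 255.0
        rgb = np.round(hsv2rgb(np.array([[[hue, sat, 0.8]]])) * 255).astype(np.uint8)
        image[yy, xx] = rgb[0, 0]
        mask[yy, xx] = True
    return SyntheticSlide(image=image, truth_mask=mask)


def generate_annotation(bag: PatchBag, polarity: str) -> np.ndarray:
    """Patch-grid annotation mask of the requested polarity.

    polarity="tumor" marks tumor patches; polarity="normal" marks the rest —
    mirroring annotation sets in which some slides delineate malignant
    epithelium and others highlight normal/stromal tissue.
    """
    if bag.tumor_flags is None:
        raise ValueError("bag has no tumor_flags ground truth")
    if polarity == "tumor":
        return bag.tumor_flags.astype(np.uint8)
    if polarity == "normal":
        return (1 - bag.tumor_flags).astype(np.uint8)
    raise ValueError(f"unknown polarity {polarity!r}")


# ---------------------------------------------------------------------------
# HDF5 / manifest I/O
# ---------------------------------------------------------------------------

def write_bag(path: str | Path, bag: PatchBag) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=bag.features.astype(np.float32))
        f.create_dataset("coords", data=bag.coords.astype(np.int32))
        if bag.tumor_flags is not None:
            f.create_dataset("tumor_flags", data=bag.tumor_flags)
        f.attrs["slide_id"] = bag.slide_id
        f.attrs["label"] = bag.label


def read_bag(path: str | Path) -> PatchBag:
    with h5py.File(path, "r") as f:
        flags = f["tumor_flags"][:] if "tumor_flags" in f else None
        return PatchBag(
            slide_id=str(f.attrs["slide_id"]),
            features=f["features"][:],
            coords=f["coords"][:],
            label=int(f.attrs["label"]),
            tumor_flags=flags,
        )


def write_cohort(out_dir: str | Path, bags: list[PatchBag]) -> pd.DataFrame:
    """Write one HDF5 per slide plus a manifest CSV; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for bag in bags:
        path = out / f"{bag.slide_id}.h5"
        write_bag(path, bag)
        rows.append(
            {"slide_id": bag.slide_id, "label": bag.label,
             "n_patches": bag.n_patches, "path": str(path)}
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[PatchBag]:
    manifest = pd.read_csv(manifest_path)
    return [read_bag(p) for p in manifest["path"]]
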