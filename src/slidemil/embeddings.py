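"""Pluggable patch-embedder interface.

The pipeline is agnostic to where patch embeddings come from: large frozen
pathology encoders produce 768- or 1024-dimensional vectors per patch, and
downstream modules only see the (N, out_dim) matrix. This module defines the
embedder contract, a registry for external plugins, and a deterministic
synthetic embedder (a fixed random projection of coarse pixel statistics)
so the whole pipeline runs end to end with no pretrained weights.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable

import numpy as np
from skimage.measure import block_reduce

__all__ = ["EmbedderSpec", "embed_patches", "register_embedder"]


@dataclass(frozen=True)
class EmbedderSpec:
    name: str
    out_dim: int = 1024  # 768 or 1024 mirror typical frozen encoders
    kind: str = "synthetic"  # {"synthetic", "external-plugin"}

    def __post_init__(self):
        if self.out_dim < 1:
            raise ValueError("out_dim must be positive")


# plugin registry: name -> callable (patches, spec) -> (N, out_dim)
_PLUGINS: dict[str, Callable] = {}


def register_embedder(name: str, fn: Callable) -> None:
    """Register an external embedder plugin (e.g. a real foundation model)."""
    _PLUGINS[name] = fn


def _projection(spec: EmbedderSpec, in_dim: int) -> np.ndarray:
    # fixed projection derived from the spec identity; never trained
    seed = zlib.crc32(f"{spec.name}:{spec.out_dim}".encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    return rng.standard_normal((in_dim, spec.out_dim)) / np.sqrt(in_dim)


def _synthetic_embed(patches: np.ndarray, spec: EmbedderSpec) -> np.ndarray:
    """Deterministic embedding of standardized patches.

    Each patch (H, W, 3) is reduced to per-channel 14x14 block means plus
    global channel means/stds, then passed through a fixed random projection
    and a tanh squash. Identical patches map to identical rows.
    """
    patches = np.asarray(patches, dtype=np.float64)
    if patches.ndim == 3:
        patches = patches[None]
    n, h, w, _ = patches.shape
    fh, fw = max(h // 14, 1), max(w // 14, 1)
    feats = []
    for p in patches:
        coarse = block_reduce(p, (fh, fw, 1), func=np.mean).ravel()
        stats = np.concatenate([p.mean(axis=(0, 1)), p.std(axis=(0, 1))])
        feats.append(np.concatenate([coarse, stats]))
    x = np.stack(feats)
    proj = _projection(spec, x.shape[1])
    return np.tanh(x @ proj)


def embed_patches(patches: np.ndarray, spec: EmbedderSpec) -> np.ndarray:
    """Map standardized patches to an (N, out_dim) embedding matrix.

    The embedder is frozen by contract: it holds no trainable state and is a
    pure function of its inputs and the spec.
    """
    if spec.kind == "synthetic":
        return _synthetic_embed(patches, spec)
    if spec.name in _PLUGINS:
        return np.asarray(_PLUGINS[spec.name](patches, spec))
    raise ValueError(f"unknown embedder {spec.name!r} (kind={spec.kind})")
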