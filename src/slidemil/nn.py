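"""Neural-network building blocks on top of the autodiff engine.

Layers follow the usual conventions: Linear with uniform fan-in init,
post-norm transformer encoder layers (self-attention -> add & norm ->
feed-forward -> add & norm), inverted dropout driven by an explicit
numpy Generator so every forward pass is reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "Dropout",
    "MultiheadSelfAttention",
    "TransformerEncoderLayer",
]


class Module:
    """Base class: recursive parameter collection and state (de)serialization."""

    def parameters(self) -> list[Tensor]:
        out = []
        for _, p in self.named_parameters():
            out.append(p)
        return out

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.named_parameters():
            p.data[...] = state[k]


def _param(rng: np.random.Generator, shape, bound: float) -> Tensor:
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_dim)
        self.weight = _param(rng, (in_dim, out_dim), bound)
        self.bias = _param(rng, (out_dim,), bound)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta, eps=self.eps)


class Dropout(Module):
    """Inverted dropout; the mask comes from the rng passed at call time."""

    def __init__(self, p: float):
        self.p = float(p)

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator) -> Tensor:
        if not training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class MultiheadSelfAttention(Module):
    """Standard scaled dot-product self-attention, d_model split across heads."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        assert d_model % n_heads == 0
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q_proj = Linear(d_model, d_model, rng)
        self.k_proj = Linear(d_model, d_model, rng)
        self.v_proj = Linear(d_model, d_model, rng)
        self.out_proj = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        s, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:  # (S, D) -> (H, S, Dh)
            return t.reshape(s, h, dh).transpose(1, 0, 2)

        q, k, v = split(self.q_proj(x)), split(self.k_proj(x)), split(self.v_proj(x))
        scores = (q @ k.transpose(0, 2, 1)) / np.sqrt(dh)
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(1, 0, 2).reshape(s, d)
        return self.out_proj(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer with a two-layer feed-forward block."""

    def __init__(
        self,
        d_model: int,
        n_heads: int,
        ffn_dim: int,
        dropout: float,
        rng: np.random.Generator,
    ):
        self.attn = MultiheadSelfAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.ffn1 = Linear(d_model, ffn_dim, rng)
        self.ffn2 = Linear(ffn_dim, d_model, rng)
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator) -> Tensor:
        x = self.ln1(x + self.drop(self.attn(x), training, rng))
        ff = self.ffn2(self.drop(self.ffn1(x).relu(), training, rng))
        return self.ln2(x + self.drop(ff, training, rng))
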