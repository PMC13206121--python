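"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the MIL aggregators need: broadcasted
arithmetic, (batched) matrix products, pointwise nonlinearities, reductions,
softmax / log-softmax, layer normalization, shape manipulation and row
gathering. Gradients are accumulated by a topological backward sweep from a
scalar loss. Arrays are float64 throughout; dropout is applied as
multiplication by an externally drawn constant mask so that training is fully
reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "clip_grad_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (the inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- helpers -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _make(cls, data, parents, backward):
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def bwd(g, a=self, b=other):
            a._accum(g)
            b._accum(g)

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            a._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bwd(g, a=self, b=other):
            a._accum(g * b.data)
            b._accum(g * a.data)

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        assert np.isscalar(scalar)
        return self * (1.0 / scalar)

    def pow(self, exponent: float) -> "Tensor":
        """Elementwise power with a scalar exponent."""
        # exponents used here are gamma >= 0 on values in [0,1]; guard the
        # 0^negative case that arises when s < 1 at exactly zero
        def bwd_simple(g, a=self, s=exponent):
            if s == 0:
                return
            with np.errstate(divide="ignore", invalid="ignore"):
                gr = s * np.power(a.data, s - 1)
            gr = np.where(np.isfinite(gr), gr, 0.0)
            a._accum(g * gr)

        return self._make(np.power(self.data, exponent), (self,), bwd_simple)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bwd(g, a=self, b=other):
            ad, bd = a.data, b.data
            if a.requires_grad:
                if bd.ndim == 1:  # (..., k) @ (k,) -> (...)
                    ga = np.expand_dims(g, -1) * bd
                else:
                    ga = g @ np.swapaxes(bd, -1, -2)
                a._accum(_unbroadcast(ga, ad.shape))
            if b.requires_grad:
                if ad.ndim == 1 and bd.ndim >= 2:  # (k,) @ (k, n) -> (n,)
                    gb = np.outer(ad, g)
                elif bd.ndim == 1:  # (..., k) @ (k,)
                    gb = (np.expand_dims(g, -1) * ad).reshape(-1, ad.shape[-1]).sum(0)
                else:
                    gb = np.swapaxes(ad, -1, -2) @ g
                b._accum(_unbroadcast(gb, bd.shape))

        return self._make(self.data @ other.data, (self, other), bwd)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bwd(g, a=self, m=mask):
            a._accum(g * m)

        return self._make(self.data * mask, (self,), bwd)

    def tanh(self):
        y = np.tanh(self.data)

        def bwd(g, a=self, y=y):
            a._accum(g * (1.0 - y * y))

        return self._make(y, (self,), bwd)

    def sigmoid(self):
        y = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def bwd(g, a=self, y=y):
            a._accum(g * y * (1.0 - y))

        return self._make(y, (self,), bwd)

    def exp(self):
        y = np.exp(self.data)

        def bwd(g, a=self, y=y):
            a._accum(g * y)

        return self._make(y, (self,), bwd)

    def log(self):
        def bwd(g, a=self):
            a._accum(g / a.data)

        return self._make(np.log(self.data), (self,), bwd)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g, a=self, ax=axis, kd=keepdims):
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def amax(self, axis: int):
        """Max-reduction along `axis`; gradient flows to the (first) argmax."""
        idx = np.argmax(self.data, axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        out = np.squeeze(out, axis=axis)

        def bwd(g, a=self, ax=axis, idx=idx):
            full = np.zeros_like(a.data)
            np.put_along_axis(
                full, np.expand_dims(idx, ax), np.expand_dims(g, ax), axis=ax
            )
            a._accum(full)

        return self._make(out, (self,), bwd)

    # -- softmax family ----------------------------------------------------
    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def bwd(g, a=self, y=y, ax=axis):
            dot = (g * y).sum(axis=ax, keepdims=True)
            a._accum(y * (g - dot))

        return self._make(y, (self,), bwd)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        y = z - lse

        def bwd(g, a=self, y=y, ax=axis):
            a._accum(g - np.exp(y) * g.sum(axis=ax, keepdims=True))

        return self._make(y, (self,), bwd)

    # -- shape -------------------------------------------------------------
    def reshape(self, *shape):
        def bwd(g, a=self):
            a._accum(g.reshape(a.data.shape))

        return self._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g, a=self, inv=inv):
            a._accum(g.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), bwd)

    def take_rows(self, indices):
        """Gather rows along axis 0 (differentiable scatter-add backward)."""
        indices = np.asarray(indices)

        def bwd(g, a=self, idx=indices):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return self._make(self.data[indices], (self,), bwd)

    @staticmethod
    def concat(tensors, axis: int = 0):
        tensors = [Tensor._wrap(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]
        offs = np.cumsum([0] + sizes)

        def bwd(g, ts=tensors, offs=offs, ax=axis):
            for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(lo, hi)
                t._accum(g[tuple(sl)])

        return Tensor._make(
            np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd
        )

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalize over the last axis, then scale and shift."""
        mu = self.data.mean(axis=-1, keepdims=True)
        var = self.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (self.data - mu) * inv
        out = gamma.data * xhat + beta.data
        d = self.data.shape[-1]

        def bwd(g, a=self, ga=gamma, be=beta, xhat=xhat, inv=inv, d=d):
            axes = tuple(range(g.ndim - 1))
            ga._accum((g * xhat).sum(axis=axes))
            be._accum(g.sum(axis=axes))
            if a.requires_grad:
                dxhat = g * ga.data
                term = (
                    dxhat
                    - dxhat.mean(axis=-1, keepdims=True)
                    - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
                )
                a._accum(term * inv)

        return self._make(out, (self, gamma, beta), bwd)

    # -- backward ----------------------------------------------------------
    def backward(self):
        assert self.data.size == 1, "backward() requires a scalar"
        topo, seen = [], set()

        def visit(t):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most `max_norm`."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            gr = p.grad.ravel()
            total += float(np.dot(gr, gr))
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    """Adam with classic L2 weight decay folded into the gradient.

    Parameter arrays are re-bound as views into one contiguous buffer so the
    moment updates run as a few large vectorized operations instead of many
    small per-parameter ones.
    """

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.buf = np.concatenate([p.data.ravel() for p in self.params])
        self._slices = []
        off = 0
        for p in self.params:
            n = p.data.size
            p.data = self.buf[off : off + n].reshape(p.data.shape)
            self._slices.append((off, n))
            off += n
        self.gbuf = np.zeros_like(self.buf)
        self.m = np.zeros_like(self.buf)
        self.v = np.zeros_like(self.buf)
        self._tmp = np.zeros_like(self.buf)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        g, tmp = self.gbuf, self._tmp
        for p, (off, n) in zip(self.params, self._slices):
            if p.grad is None:
                g[off : off + n] = 0.0
            else:
                g[off : off + n] = p.grad.ravel()
        if self.weight_decay:
            np.multiply(self.buf, self.weight_decay, out=tmp)
            g += tmp
        self.m *= self.b1
        np.multiply(g, 1.0 - self.b1, out=tmp)
        self.m += tmp
        self.v *= self.b2
        np.multiply(g, g, out=tmp)
        tmp *= 1.0 - self.b2
        self.v += tmp
        # lr*(m/b1t)/(sqrt(v/b2t)+eps) == c*m/(sqrt(v)+eps2) with the scalars
        c = self.lr * np.sqrt(b2t) / b1t
        eps2 = self.eps * np.sqrt(b2t)
        np.sqrt(self.v, out=tmp)
        tmp += eps2
        np.divide(self.m, tmp, out=tmp)
        tmp *= c
        self.buf -= tmp
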