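"""The six MIL aggregation heads and their complexity accounting.

All aggregators share an input projection fc1 (in_dim -> 512, ReLU, dropout)
and map a bag of N instance embeddings to C class logits:

* ``meanpool`` / ``maxpool`` — elementwise mean/max over projected instances,
  followed by a 512 -> 256 -> C classifier.
* ``abmil`` — gated attention a_i ∝ exp(w^T(tanh(V h_i) ⊙ σ(U h_i))) with a
  single 512 -> C classifier on the attention-weighted bag vector.
* ``clam_sb`` — ABMIL plus C per-class instance heads (512 -> 2) used for an
  auxiliary instance-level loss on the highest/lowest-attention patches.
* ``dsmil`` — dual stream: a per-instance classifier max-pooled per class,
  plus a bag stream attending to each class's critical instance; the final
  logits average the two streams.
* ``dtp_transmil`` — dynamic top-proportion transformer: a scorer ranks all
  instances, the top k_eff(N) = min(N, clamp(floor(0.25 N), 100, 2000)) are
  gated by their sigmoid scores and fed (with a learnable CLS token, no
  positional encoding) through a 2-layer, 8-head transformer encoder.

``count_parameters`` / ``count_flops`` implement the accounting used to
compare aggregator complexity; FLOPs follow the convention of 2·in·out per
token per affine map and 1 per element for activations, pooling reductions
and attention weighting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .autodiff import Tensor
from .nn import Dropout, LayerNorm, Linear, Module, TransformerEncoderLayer

__all__ = [
    "AGGREGATOR_NAMES",
    "DTPParams",
    "AggregatorSpec",
    "k_eff",
    "build_aggregator",
    "count_parameters",
    "parameter_breakdown",
    "count_flops",
    "attention_scores",
    "save_model",
    "load_model",
]

AGGREGATOR_NAMES = ("meanpool", "maxpool", "abmil", "clam_sb", "dsmil", "dtp_transmil")


@dataclass(frozen=True)
class DTPParams:
    ratio: float = 0.25
    k_min: int = 100
    k_max: int = 2000
    d_model: int = 512
    heads: int = 8
    layers: int = 2
    ffn_dim: int = 1024

    def __post_init__(self):
        if not (0.0 < self.ratio <= 1.0):
            raise ValueError("ratio must be in (0, 1]")
        if self.k_min > self.k_max:
            raise ValueError("k_min must not exceed k_max")


@dataclass(frozen=True)
class AggregatorSpec:
    name: str
    in_dim: int = 1024
    n_classes: int = 4
    proj_dim: int = 512
    cls_hidden: int = 256
    attn_hidden: int = 256  # gated-attention hidden width
    scorer_hidden: int = 256  # DTP scorer hidden width
    dsmil_query_dim: int = 128
    dtp: DTPParams = field(default_factory=DTPParams)
    dropout_fc1: float = 0.25
    dropout_cls: float = 0.1
    dropout_enc: float = 0.1
    clam_k_inst: int = 8  # instances per attention pole for the instance loss

    def __post_init__(self):
        if self.name not in AGGREGATOR_NAMES:
            raise ValueError(f"unknown aggregator {self.name!r}")
        for d in (self.in_dim, self.n_classes, self.proj_dim, self.cls_hidden):
            if d < 1:
                raise ValueError("all dimensions must be positive")


def k_eff(n: int, dtp: DTPParams | None = None) -> int:
    """Number of instances the dynamic top-proportion rule selects.

    k = min(N, clamp(floor(ratio*N), k_min, k_max)); floor semantics put the
    proportional-regime/floor boundary at N = k_min/ratio and the saturation
    onset at N* = k_max/ratio.
    """
    dtp = dtp or DTPParams()
    if n < 1:
        raise ValueError("bag size must be at least 1")
    return min(n, min(dtp.k_max, max(dtp.k_min, int(dtp.ratio * n))))


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class AggregatorModel(Module):
    """Common scaffolding: spec, rng (init + dropout), shared fc1 projection."""

    def __init__(self, spec: AggregatorSpec, seed: int = 0):
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        self.fc1 = Linear(spec.in_dim, spec.proj_dim, self.rng)
        self.drop_fc1 = Dropout(spec.dropout_fc1)

    def _project(self, x: np.ndarray, training: bool) -> Tensor:
        h = self.fc1(Tensor(np.asarray(x, dtype=np.float64))).relu()
        return self.drop_fc1(h, training, self.rng)

    def forward(self, x: np.ndarray, training: bool = False):
        raise NotImplementedError

    def __call__(self, x, training=False):
        return self.forward(x, training=training)


class _MLPHead(Module):
    """512 -> 256 -> C classifier with ReLU and dropout."""

    def __init__(self, spec: AggregatorSpec, rng):
        self.fc = Linear(spec.proj_dim, spec.cls_hidden, rng)
        self.out = Linear(spec.cls_hidden, spec.n_classes, rng)
        self.drop = Dropout(spec.dropout_cls)

    def __call__(self, x, training, rng):
        return self.out(self.drop(self.fc(x).relu(), training, rng))


class PoolingAggregator(AggregatorModel):
    def __init__(self, spec: AggregatorSpec, seed: int = 0):
        super().__init__(spec, seed)
        self.classifier = _MLPHead(spec, self.rng)

    def forward(self, x, training=False):
        h = self._project(x, training)
        pooled = h.mean(axis=0) if self.spec.name == "meanpool" else h.amax(axis=0)
        logits = self.classifier(pooled, training, self.rng)
        return logits, {"attention": None}


class ABMIL(AggregatorModel):
    def __init__(self, spec: AggregatorSpec, seed: int = 0):
        super().__init__(spec, seed)
        self.attn_V = Linear(spec.proj_dim, spec.attn_hidden, self.rng)
        self.attn_U = Linear(spec.proj_dim, spec.attn_hidden, self.rng)
        self.attn_w = Linear(spec.attn_hidden, 1, self.rng)
        self.classifier = Linear(spec.proj_dim, spec.n_classes, self.rng)

    def _attend(self, h: Tensor):
        gate = self.attn_V(h).tanh() * self.attn_U(h).sigmoid()
        a = self.attn_w(gate).softmax(axis=0)  # (N, 1), sums to 1
        bag = (a * h).sum(axis=0)
        return a, bag

    def forward(self, x, training=False):
        h = self._project(x, training)
        a, bag = self._attend(h)
        logits = self.classifier(bag)
        return logits, {"attention": a.data.ravel().copy(), "h": h, "a": a}


class CLAMSB(ABMIL):
    """ABMIL with per-class instance heads for the clustering-style loss."""

    def __init__(self, spec: AggregatorSpec, seed: int = 0):
        super().__init__(spec, seed)
        self.instance_heads = [
            Linear(spec.proj_dim, 2, self.rng) for _ in range(spec.n_classes)
        ]

    def instance_loss(self, aux: dict, label: int) -> Tensor:
        """Cross-entropy on the k highest- (label 1) and lowest- (label 0)
        attention instances under the true class's head."""
        h, a = aux["h"], aux["a"]
        n = h.shape[0]
        k = min(self.spec.clam_k_inst, max(n // 2, 1))
        order = np.argsort(a.data.ravel(), kind="stable")
        lo, hi = order[:k], order[-k:]
        sel = np.concatenate([hi, lo])
        targets = np.concatenate([np.ones(len(hi)), np.zeros(len(lo))]).astype(int)
        logits = self.instance_heads[label](h.take_rows(sel))  # (2k, 2)
        logp = logits.log_softmax(axis=1)
        picked = logp * Tensor(np.eye(2)[targets])
        return -(picked.sum() / len(targets))


class DSMIL(AggregatorModel):
    def __init__(self, spec: AggregatorSpec, seed: int = 0):
        super().__init__(spec, seed)
        self.instance_head = Linear(spec.proj_dim, spec.n_classes, self.rng)
        self.query = Linear(spec.proj_dim, spec.dsmil_query_dim, self.rng)
        self.bag_head = Linear(spec.proj_dim, spec.n_classes, self.rng)

    def forward(self, x, training=False):
        c = self.spec.n_classes
        h = self._project(x, training)
        inst_logits = self.instance_head(h)  # (N, C)
        inst_stream = inst_logits.amax(axis=0)  # (C,)
        q = self.query(h)  # (N, Dq)
        crit = np.argmax(inst_logits.data, axis=0)  # critical instance per class
        attns, bag_rows = [], []
        for cls in range(c):
            qm = q.take_rows([int(crit[cls])])  # (1, Dq)
            scores = q @ qm.transpose(1, 0)  # (N, 1) inner products
            a = scores.softmax(axis=0)
            attns.append(a.data.ravel().copy())
            bag_rows.append((a * h).sum(axis=0).reshape(1, -1))
        bags = Tensor.concat(bag_rows, axis=0)  # (C, 512)
        full = self.bag_head(bags)  # (C, C)
        diag = (full * Tensor(np.eye(c))).sum(axis=1)
        logits = 0.5 * (inst_stream + diag)
        pred = int(np.argmax(logits.data))
        return logits, {"attention": attns[pred], "attention_per_class": attns}


class DTPTransMIL(AggregatorModel):
    def __init__(self, spec: AggregatorSpec, seed: int = 0):
        super().__init__(spec, seed)
        d = spec.dtp
        self.scorer_fc = Linear(spec.proj_dim, spec.scorer_hidden, self.rng)
        self.scorer_out = Linear(spec.scorer_hidden, 1, self.rng)
        self.pre_ln = LayerNorm(d.d_model)
        self.cls_token = Tensor(
            self.rng.uniform(-0.02, 0.02, size=(1, d.d_model)), requires_grad=True
        )
        self.encoder = [
            TransformerEncoderLayer(d.d_model, d.heads, d.ffn_dim,
                                    spec.dropout_enc, self.rng)
            for _ in range(d.layers)
        ]
        self.final_ln = LayerNorm(d.d_model)
        self.classifier = _MLPHead(spec, self.rng)

    def forward(self, x, training=False):
        n = np.asarray(x).shape[0]
        h = self._project(x, training)
        s = self.scorer_out(self.scorer_fc(h).tanh())  # (N, 1)
        s_np = s.data.ravel()
        k = k_eff(n, self.spec.dtp)
        # rank by descending score; ties broken by ascending instance index
        order = np.lexsort((np.arange(n), -s_np))
        sel = order[:k]
        tokens = self.pre_ln(h.take_rows(sel) * s.take_rows(sel).sigmoid())
        seq = Tensor.concat([self.cls_token, tokens], axis=0)
        for layer in self.encoder:
            seq = layer(seq, training, self.rng)
        seq = self.final_ln(seq)
        cls_out = seq.take_rows([0]).reshape(-1)
        logits = self.classifier(cls_out, training, self.rng)
        sig = 1.0 / (1.0 + np.exp(-s_np))
        return logits, {"attention": sig, "selected": sel}


_BUILDERS = {
    "meanpool": PoolingAggregator,
    "maxpool": PoolingAggregator,
    "abmil": ABMIL,
    "clam_sb": CLAMSB,
    "dsmil": DSMIL,
    "dtp_transmil": DTPTransMIL,
}


def build_aggregator(spec: AggregatorSpec, seed: int = 0) -> AggregatorModel:
    return _BUILDERS[spec.name](spec, seed=seed)


def count_parameters(spec: AggregatorSpec) -> int:
    """Exact number of trainable scalars in build_aggregator(spec)."""
    return build_aggregator(spec).n_parameters()


def parameter_breakdown(spec: AggregatorSpec) -> dict[str, float]:
    """Per-component parameter counts plus their share of the total.

    Components are the model's top-level blocks (fc1, attention, scorer,
    encoder, classifier, ...); shares are fractions of the total count.
    """
    model = build_aggregator(spec)
    groups: dict[str, int] = {}
    for name, p in model.named_parameters():
        top = name.split(".")[0]
        if top in ("attn_V", "attn_U", "attn_w"):
            top = "attention"
        elif top in ("scorer_fc", "scorer_out"):
            top = "scorer"
        elif top in ("instance_heads", "instance_head"):
            top = "instance_heads"
        groups[top] = groups.get(top, 0) + p.size
    total = sum(groups.values())
    out = {f"{k}": v for k, v in groups.items()}
    out["total"] = total
    for k, v in list(groups.items()):
        out[f"{k}_share"] = v / total
    return out


# ---------------------------------------------------------------------------
# FLOP accounting
# ---------------------------------------------------------------------------

def _affine(in_dim: int, out_dim: int, tokens: int = 1) -> float:
    return 2.0 * in_dim * out_dim * tokens


def count_flops(spec: AggregatorSpec, n: int) -> float:
    """Forward-pass cost in GFLOPs at bag size ``n``.

    Convention: an affine map in->out over T tokens costs 2*in*out*T; every
    elementwise activation, pooling reduction or attention weighting costs 1
    per element; attention score maps and softmaxes are counted per element.
    Dropout and bias additions are not counted separately.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    p, c, hdim = spec.proj_dim, spec.n_classes, spec.cls_hidden
    total = _affine(spec.in_dim, p, n) + p * n  # fc1 + ReLU

    def mlp_head(tokens: int = 1) -> float:
        return _affine(p, hdim, tokens) + hdim * tokens + _affine(hdim, c, tokens)

    name = spec.name
    if name in ("meanpool", "maxpool"):
        total += p * n  # pooling reduction
        total += mlp_head()
    elif name in ("abmil", "clam_sb"):
        # gated attention (instance heads of clam_sb are not used at inference)
        ah = spec.attn_hidden
        total += 2 * _affine(p, ah, n) + 3 * ah * n  # V, U, tanh/sigmoid/gate
        total += _affine(ah, 1, n) + n  # w + softmax
        total += 2 * p * n  # attention weighting + reduction
        total += _affine(p, c)
    elif name == "dsmil":
        dq = spec.dsmil_query_dim
        total += _affine(p, c, n) + c * n  # instance head + max reduction
        total += _affine(p, dq, n)  # query map
        total += c * (_affine(dq, 1, n) + n + 2 * p * n)  # per-class attention
        total += _affine(p, c, c)  # bag head on C bag vectors
    elif name == "dtp_transmil":
        d = spec.dtp
        k = k_eff(n, d)
        s = k + 1  # CLS + selected tokens
        sh = spec.scorer_hidden
        total += _affine(p, sh, n) + sh * n + _affine(sh, 1, n)  # scorer
        total += 2 * d.d_model * k  # sigmoid gate + weighting
        total += d.d_model * k  # pre-encoder layer norm
        dh = d.d_model // d.heads
        for _ in range(d.layers):
            total += 4 * _affine(d.d_model, d.d_model, s)  # q, k, v, out
            total += 2 * d.heads * dh * s * s  # scores qk^T
            total += d.heads * s * s  # softmax
            total += 2 * d.heads * dh * s * s  # attn @ v
            total += 2 * _affine(d.d_model, d.ffn_dim, s) + d.ffn_dim * s  # ffn
            total += 4 * d.d_model * s  # residual adds + two layer norms
        total += d.d_model * s  # final layer norm
        total += mlp_head()
    return total / 1e9


def attention_scores(model: AggregatorModel, bag: np.ndarray) -> Optional[np.ndarray]:
    """Per-instance attention for a bag, or None for pooling aggregators.

    ABMIL/CLAM return softmax attention (sums to 1); DTP-TransMIL returns the
    sigmoid scorer output for every instance, selected or not; DSMIL returns
    its bag-stream attention for the predicted class.
    """
    _, aux = model.forward(bag, training=False)
    return aux["attention"]


# ---------------------------------------------------------------------------
# checkpoints: npz weights + JSON spec sidecar
# ---------------------------------------------------------------------------

def save_model(path: str | Path, model: AggregatorModel) -> None:
    path = Path(path)
    state = {k.replace(".", "__"): v for k, v in model.state_dict().items()}
    np.savez(path.with_suffix(".npz"), **state)
    spec = model.spec
    doc = {
        "name": spec.name, "in_dim": spec.in_dim, "n_classes": spec.n_classes,
        "proj_dim": spec.proj_dim, "cls_hidden": spec.cls_hidden,
        "attn_hidden": spec.attn_hidden, "scorer_hidden": spec.scorer_hidden,
        "dsmil_query_dim": spec.dsmil_query_dim,
        "dtp": vars(spec.dtp) if not isinstance(spec.dtp, dict) else spec.dtp,
        "dropout_fc1": spec.dropout_fc1, "dropout_cls": spec.dropout_cls,
        "dropout_enc": spec.dropout_enc, "clam_k_inst": spec.clam_k_inst,
    }
    path.with_suffix(".json").write_text(json.dumps(doc, indent=2))


def load_model(path: str | Path) -> AggregatorModel:
    path = Path(path)
    doc = json.loads(path.with_suffix(".json").read_text())
    doc["dtp"] = DTPParams(**doc["dtp"])
    spec = AggregatorSpec(**doc)
    model = build_aggregator(spec)
    data = np.load(path.with_suffix(".npz"))
    model.load_state_dict({k.replace("__", "."): data[k] for k in data.files})
    return model
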