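"""Imbalance-aware MIL training protocol.

Focal loss with inverse-frequency class weights, Adam with linear warmup and
cosine annealing, gradient clipping, early stopping on a validation metric
(AUROC for binary HGSC-vs-rest, balanced accuracy otherwise), stratified
k-fold assignments held fixed across methods, and the gamma x p focal-loss
sensitivity sweep harness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .aggregators import AggregatorModel, AggregatorSpec, build_aggregator
from .autodiff import Adam, Tensor, clip_grad_norm

__all__ = [
    "TrainConfig",
    "FoldAssignment",
    "class_weights",
    "focal_loss",
    "lr_at",
    "make_folds",
    "build_fold_assignment",
    "train_model",
    "predict_proba",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-4
    epochs: int = 150
    warmup_epochs: int = 15
    patience: int = 30
    focal_gamma: float = 2.0
    weight_exponent: float = 1.5
    grad_clip_norm: float = 1.0
    batch_bags: int = 1
    monitor: str = "balanced_accuracy"  # or "auroc"
    seed: int = 0
    fp16: bool = False  # accepted for interface parity; arithmetic stays float64

    def __post_init__(self):
        if self.warmup_epochs >= self.epochs:
            raise ValueError("warmup_epochs must be smaller than epochs")
        if self.focal_gamma < 0 or self.weight_exponent < 0:
            raise ValueError("gamma and weight exponent must be non-negative")
        if self.monitor not in ("auroc", "balanced_accuracy"):
            raise ValueError(f"unknown monitor {self.monitor!r}")


@dataclass
class FoldAssignment:
    """Per-slide fold indices for the three tasks, from one seed.

    ``stage1`` covers all slides (binary HGSC-vs-rest stratification),
    ``stage2`` covers non-HGSC slides only (-1 for HGSC slides; 4-class
    stratification), ``flat`` covers all slides (5-class stratification).
    """

    stage1: np.ndarray
    stage2: np.ndarray
    flat: np.ndarray
    k: int
    seed: int


def class_weights(counts: Sequence[int], exponent: float) -> np.ndarray:
    """Inverse-frequency weights w_c = (1/f_c)^p, renormalized to mean 1."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 1).any():
        raise ValueError("every class must have at least one sample")
    freq = counts / counts.sum()
    w = (1.0 / freq) ** exponent
    return w / w.mean()


def focal_loss(
    probs: np.ndarray,
    targets: np.ndarray,
    gamma: float = 2.0,
    weights: Optional[np.ndarray] = None,
    eps: float = 1e-12,
) -> float:
    """Batch-mean focal loss -w_y (1 - p_y)^gamma log p_y on probabilities.

    With gamma = 0 and unit weights this is the standard cross-entropy.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    targets = np.atleast_1d(np.asarray(targets, dtype=int))
    p_y = np.clip(probs[np.arange(len(targets)), targets], eps, 1.0)
    w = np.ones(probs.shape[1]) if weights is None else np.asarray(weights, float)
    terms = -w[targets] * (1.0 - p_y) ** gamma * np.log(p_y)
    return float(terms.mean())


def _focal_loss_logits(
    logits: Tensor, target: int, gamma: float, weight: float
) -> Tensor:
    """Autodiff focal loss for a single bag, from raw logits."""
    logp = logits.log_softmax(axis=-1)
    onehot = np.zeros(logits.shape[-1])
    onehot[target] = 1.0
    lp_y = (logp * Tensor(onehot)).sum()
    p_y = lp_y.exp()
    return -weight * (1.0 - p_y).pow(gamma) * lp_y


def lr_at(epoch: int, config: TrainConfig) -> float:
    """Learning rate at an epoch: linear warmup then cosine annealing.

    The ramp reaches the base rate at the last warmup epoch, where the cosine
    phase starts at exactly the base rate (continuous junction).
    """
    if not (0 <= epoch < config.epochs):
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    wu = config.warmup_epochs
    if epoch < wu:
        return config.lr * (epoch + 1) / wu
    span = config.epochs - wu
    return config.lr * 0.5 * (1.0 + np.cos(np.pi * (epoch - wu) / span))


def make_folds(
    labels: Sequence[int], k: int = 5, seed: int = 0
) -> np.ndarray:
    """Stratified fold index per sample; deterministic in the seed."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot stratify into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(labels), dtype=int)
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        folds[val_idx] = fold
    return folds


def build_fold_assignment(labels: Sequence[int], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Fold assignments for stage 1 (binary, all slides), stage 2 (non-HGSC
    only, 4-class) and the flat 5-class task, all from the same seed."""
    labels = np.asarray(labels)
    binary = (labels == 0).astype(int)  # HGSC is label 0
    stage1 = make_folds(binary, k=k, seed=seed)
    stage2 = np.full(len(labels), -1, dtype=int)
    non_hgsc = np.flatnonzero(labels != 0)
    stage2[non_hgsc] = make_folds(labels[non_hgsc], k=k, seed=seed)
    flat = make_folds(labels, k=k, seed=seed)
    return FoldAssignment(stage1=stage1, stage2=stage2, flat=flat, k=k, seed=seed)


def predict_proba(model: AggregatorModel, bags: Sequence[np.ndarray]) -> np.ndarray:
    """Softmax class probabilities per bag, eval mode (no dropout)."""
    out = []
    for x in bags:
        logits, _ = model.forward(x, training=False)
        z = logits.data - logits.data.max()
        e = np.exp(z)
        out.append(e / e.sum())
    return np.stack(out)


def _val_metric(model, bags, labels, monitor: str) -> float:
    probs = predict_proba(model, bags)
    if monitor == "auroc":
        return float(roc_auc_score(labels, probs[:, 1]))
    return float(balanced_accuracy_score(labels, probs.argmax(axis=1)))


def train_model(
    bags: Sequence[np.ndarray],
    labels: Sequence[int],
    spec: AggregatorSpec,
    config: TrainConfig,
    train_idx: Sequence[int],
    val_idx: Sequence[int],
) -> tuple[AggregatorModel, pd.DataFrame]:
    """Train one aggregator on a train split, early-stopping on the val split.

    Returns the model restored to its best-validation epoch and a history
    table (epoch, train_loss, val_metric, lr). Fully deterministic in
    ``config.seed``.
    """
    labels = np.asarray(labels)
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("empty train or validation split")
    if np.intersect1d(train_idx, val_idx).size:
        raise ValueError("train and validation splits overlap")
    y_train = labels[train_idx]
    classes, counts = np.unique(y_train, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training split contains a single class")
    if len(classes) != spec.n_classes:
        raise ValueError(
            f"training labels cover {len(classes)} classes, spec has {spec.n_classes}"
        )
    weights = class_weights(counts, config.weight_exponent)

    model = build_aggregator(spec, seed=config.seed)
    opt = Adam(
        model.parameters(), lr=config.lr, weight_decay=config.weight_decay
    )
    shuffle_rng = np.random.default_rng(config.seed + 1)
    val_bags = [bags[i] for i in val_idx]
    y_val = labels[val_idx]

    best_metric, best_state, best_epoch = -np.inf, model.state_dict(), -1
    history = []
    for epoch in range(config.epochs):
        opt.lr = lr_at(epoch, config)
        order = shuffle_rng.permutation(len(train_idx))
        losses = []
        for j in order:
            i = train_idx[j]
            logits, aux = model.forward(bags[i], training=True)
            w_i = float(weights[np.searchsorted(classes, labels[i])])
            loss = _focal_loss_logits(logits, int(labels[i]), config.focal_gamma, w_i)
            if hasattr(model, "instance_loss"):
                loss = loss + 0.3 * model.instance_loss(aux, int(labels[i]))
            opt.zero_grad()
            loss.backward()
            clip_grad_norm(model.parameters(), config.grad_clip_norm)
            opt.step()
            losses.append(loss.item())
        metric = _val_metric(model, val_bags, y_val, config.monitor)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_metric": metric, "lr": opt.lr}
        )
        if metric > best_metric:
            best_metric, best_state, best_epoch = metric, model.state_dict(), epoch
        elif epoch - best_epoch >= config.patience:
            break
    model.load_state_dict(best_state)
    return model, pd.DataFrame(history)


def sensitivity_sweep(
    gammas: Sequence[float],
    exponents: Sequence[float],
    bags: Sequence[np.ndarray],
    labels: Sequence[int],
    spec: AggregatorSpec,
    config: TrainConfig,
    folds: np.ndarray,
) -> pd.DataFrame:
    """Grid search over focal gamma x weight exponent, one run per fold.

    Emits a long-format table (gamma, weight_exponent, fold, metric, value);
    a 1x1 grid reduces to plain cross-validation.
    """
    rows = []
    for g in gammas:
        for p in exponents:
            cfg = replace(config, focal_gamma=g, weight_exponent=p)
            for fold in np.unique(folds):
                tr = np.flatnonzero(folds != fold)
                va = np.flatnonzero(folds == fold)
                model, _ = train_model(bags, labels, spec, cfg, tr, va)
                val_bags = [bags[i] for i in va]
                y_val = np.asarray(labels)[va]
                rows.append(
                    {"gamma": g, "weight_exponent": p, "fold": int(fold),
                     "metric": cfg.monitor,
                     "value": _val_metric(model, val_bags, y_val, cfg.monitor)}
                )
    return pd.DataFrame(rows)
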