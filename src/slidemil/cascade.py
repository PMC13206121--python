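"""Flat five-class baseline vs. hierarchical two-stage cascade evaluation.

The cascade routes each slide through a binary HGSC-vs-rest stage whose
operating point is the Youden-J-optimal threshold of its validation fold;
slides called HGSC are labeled immediately, the rest go to a four-class
second stage. All evaluation is out-of-fold: a slide is always scored by
the model of the fold in which it was held out.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .aggregators import AggregatorSpec
from .synthetic import SUBTYPES, CohortConfig, generate_cohort
from .training import (
    FoldAssignment,
    TrainConfig,
    build_fold_assignment,
    predict_proba,
    train_model,
)

__all__ = [
    "CascadeResult",
    "youden_threshold",
    "cascade_predict",
    "balanced_accuracy_from_confusion",
    "metric_bundle",
    "train_stage_models",
    "evaluate_cascade",
    "evaluate_flat",
    "compare_strategies",
]

# stage-2 class index -> global label (EC, CC, LGSC, MC)
_STAGE2_TO_GLOBAL = np.array([1, 2, 3, 4])


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    A positive call is score >= tau. Candidates are the observed score
    values; ties in J are broken toward the smallest tau (higher
    sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to choose a threshold")
    pos, neg = scores[labels == 1], scores[labels == 0]
    best_tau, best_j = None, -np.inf
    for tau in np.sort(np.unique(scores)):
        j = (pos >= tau).mean() + (neg < tau).mean() - 1.0
        if j > best_j + 1e-12:  # strict improvement; first (smallest) tau wins ties
            best_tau, best_j = float(tau), j
    return best_tau


def cascade_predict(
    stage1_prob: float, tau: float, stage2_probs: Sequence[float]
) -> int:
    """Final global label for one slide: HGSC iff stage-1 prob >= tau, else
    the argmax stage-2 subtype (ties toward the lowest class index)."""
    if stage1_prob >= tau:
        return 0
    p2 = np.asarray(stage2_probs, dtype=float)
    if p2.shape != (4,):
        raise ValueError("stage-2 probabilities must cover the 4 non-HGSC classes")
    return int(_STAGE2_TO_GLOBAL[int(np.argmax(p2))])


def balanced_accuracy_from_confusion(cm: np.ndarray) -> float:
    """Unweighted mean of per-class recalls from a confusion matrix."""
    cm = np.asarray(cm, dtype=float)
    support = cm.sum(axis=1)
    recalls = np.diag(cm) / np.where(support > 0, support, 1.0)
    return float(recalls[support > 0].mean())


def metric_bundle(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = 5) -> dict:
    labels = np.arange(n_classes)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    hgsc_total = int((np.asarray(y_true) == 0).sum())
    hgsc_hit = int(cm[0, 0])
    return {
        "confusion": cm,
        "per_class": pd.DataFrame(
            {"subtype": [SUBTYPES[i] for i in labels], "support": support,
             "precision": prec, "recall": rec, "f1": f1}
        ),
        "balanced_accuracy": balanced_accuracy_from_confusion(cm),
        "hgsc_recall": hgsc_hit / hgsc_total if hgsc_total else np.nan,
        "hgsc_missed": hgsc_total - hgsc_hit,
    }


@dataclass
class CascadeResult:
    per_slide: pd.DataFrame  # slide, label, s1_prob, fold, tau, routed, predicted
    thresholds: np.ndarray  # per-fold Youden tau
    confusion: np.ndarray
    per_class: pd.DataFrame
    balanced_accuracy: float
    hgsc_recall: float
    hgsc_missed: int


def train_stage_models(
    bags: Sequence[np.ndarray],
    labels: np.ndarray,
    stage: str,
    folds: FoldAssignment,
    spec: AggregatorSpec,
    config: TrainConfig,
):
    """Train the per-fold models of one task.

    stage: 'stage1' (binary HGSC-vs-rest over all slides, AUROC monitor),
    'stage2' (4-class over non-HGSC slides), or 'flat' (5-class).
    Returns a list of k trained models.
    """
    labels = np.asarray(labels)
    if stage == "stage1":
        task_labels = (labels == 0).astype(int)
        fold_idx, subset = folds.stage1, np.arange(len(labels))
        spec = replace(spec, n_classes=2)
        config = replace(config, monitor="auroc")
    elif stage == "stage2":
        subset = np.flatnonzero(labels != 0)
        task_labels = labels - 1  # 1..4 -> 0..3 on the subset
        fold_idx = folds.stage2
        spec = replace(spec, n_classes=4)
        config = replace(config, monitor="balanced_accuracy")
    elif stage == "flat":
        task_labels = labels
        fold_idx, subset = folds.flat, np.arange(len(labels))
        spec = replace(spec, n_classes=5)
        config = replace(config, monitor="balanced_accuracy")
    else:
        raise ValueError(f"unknown stage {stage!r}")

    models = []
    for fold in range(folds.k):
        tr = subset[fold_idx[subset] != fold]
        va = subset[fold_idx[subset] == fold]
        model, _ = train_model(bags, task_labels, spec, config, tr, va)
        models.append(model)
    return models


def evaluate_cascade(
    bags: Sequence[np.ndarray],
    labels: np.ndarray,
    folds: FoldAssignment,
    stage1_models: Sequence,
    stage2_models: Sequence,
) -> CascadeResult:
    """End-to-end out-of-fold cascade evaluation.

    Each slide's HGSC probability comes from the stage-1 model of its
    held-out fold and is thresholded by that fold's Youden tau. Non-routed
    non-HGSC slides are scored by their own stage-2 out-of-fold model;
    non-routed HGSC slides (stage-1 false negatives, never part of stage-2
    folds) use the stage-2 model sharing their stage-1 fold index.
    """
    labels = np.asarray(labels)
    n = len(labels)
    binary = (labels == 0).astype(int)

    s1_prob = np.empty(n)
    for fold in range(folds.k):
        idx = np.flatnonzero(folds.stage1 == fold)
        s1_prob[idx] = predict_proba(stage1_models[fold], [bags[i] for i in idx])[:, 1]

    taus = np.array(
        [
            youden_threshold(
                s1_prob[folds.stage1 == fold], binary[folds.stage1 == fold]
            )
            for fold in range(folds.k)
        ]
    )
    tau_per_slide = taus[folds.stage1]
    routed = s1_prob >= tau_per_slide

    pred = np.empty(n, dtype=int)
    pred[routed] = 0
    for i in np.flatnonzero(~routed):
        fold = folds.stage2[i] if labels[i] != 0 else folds.stage1[i]
        p2 = predict_proba(stage2_models[fold], [bags[i]])[0]
        pred[i] = _STAGE2_TO_GLOBAL[int(np.argmax(p2))]

    bundle = metric_bundle(labels, pred)
    per_slide = pd.DataFrame(
        {"label": labels, "s1_prob": s1_prob, "s1_fold": folds.stage1,
         "tau": tau_per_slide, "routed": routed, "predicted": pred}
    )
    return CascadeResult(
        per_slide=per_slide, thresholds=taus, confusion=bundle["confusion"],
        per_class=bundle["per_class"],
        balanced_accuracy=bundle["balanced_accuracy"],
        hgsc_recall=bundle["hgsc_recall"], hgsc_missed=bundle["hgsc_missed"],
    )


def evaluate_flat(
    bags: Sequence[np.ndarray],
    labels: np.ndarray,
    folds: FoldAssignment,
    flat_models: Sequence,
) -> dict:
    """Out-of-fold argmax evaluation of the flat five-class classifier."""
    labels = np.asarray(labels)
    pred = np.empty(len(labels), dtype=int)
    for fold in range(folds.k):
        idx = np.flatnonzero(folds.flat == fold)
        probs = predict_proba(flat_models[fold], [bags[i] for i in idx])
        pred[idx] = probs.argmax(axis=1)
    return metric_bundle(labels, pred)


def compare_strategies(
    cohort_config: CohortConfig,
    separations: Sequence[float],
    aggregator_names: Sequence[str],
    train_config: TrainConfig,
    spec_template: Optional[AggregatorSpec] = None,
    k: int = 5,
) -> pd.DataFrame:
    """Grid comparison: separation knob x aggregator x strategy.

    For each cell reports balanced accuracy, HGSC recall and HGSC missed
    count. Fold assignments are derived from the cohort seed and shared by
    every cell at a given separation level.
    """
    rows = []
    for rho in separations:
        cfg = replace(cohort_config, separation=rho)
        bags_obj, _ = generate_cohort(cfg)
        feats = [b.features.astype(np.float64) for b in bags_obj]
        labels = np.array([b.label for b in bags_obj])
        folds = build_fold_assignment(labels, k=k, seed=cfg.seed)
        for name in aggregator_names:
            base = spec_template or AggregatorSpec(name=name, in_dim=cfg.embed_dim)
            spec = replace(base, name=name, in_dim=cfg.embed_dim)
            s1 = train_stage_models(feats, labels, "stage1", folds, spec, train_config)
            s2 = train_stage_models(feats, labels, "stage2", folds, spec, train_config)
            fl = train_stage_models(feats, labels, "flat", folds, spec, train_config)
            cas = evaluate_cascade(feats, labels, folds, s1, s2)
            flat = evaluate_flat(feats, labels, folds, fl)
            for strategy, ba, rec, miss in (
                ("cascade", cas.balanced_accuracy, cas.hgsc_recall, cas.hgsc_missed),
                ("flat", flat["balanced_accuracy"], flat["hgsc_recall"],
                 flat["hgsc_missed"]),
            ):
                rows.append(
                    {"separation": rho, "aggregator": name, "strategy": strategy,
                     "balanced_accuracy": ba, "hgsc_recall": rec,
                     "hgsc_missed": miss}
                )
    return pd.DataFrame(rows)
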