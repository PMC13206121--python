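"""Training protocol: loss, schedule, folds, early stopping, sweep."""

import numpy as np
import pytest

import slidemil.training as training_mod
from slidemil.aggregators import AggregatorSpec
from slidemil.training import (
    TrainConfig,
    build_fold_assignment,
    class_weights,
    focal_loss,
    lr_at,
    make_folds,
    sensitivity_sweep,
    train_model,
)


def test_class_weight_examples():
    assert np.allclose(class_weights([10, 10, 10], 1.5), 1.0)
    w = class_weights([10, 90], 1.5)
    assert w[0] / w[1] == pytest.approx(9**1.5)  # = 27
    assert np.allclose(class_weights([3, 70, 200], 0.0), 1.0)
    assert class_weights([5, 5], 2.0).mean() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        class_weights([0, 10], 1.5)


def test_focal_loss_examples_and_identity():
    # p_y = 0.5, gamma = 2, unit weight: 0.25 * ln 2
    val = focal_loss(np.array([[0.5, 0.5]]), np.array([0]), gamma=2.0)
    assert val == pytest.approx(0.25 * np.log(2))
    # certain prediction: zero loss
    assert focal_loss(np.array([[1.0, 0.0]]), np.array([0]), gamma=2.0) == 0.0
    # gamma=0, unit weights == cross-entropy to 1e-12 on random inputs
    rng = np.random.default_rng(0)
    probs = rng.dirichlet(np.ones(4), size=50)
    t = rng.integers(0, 4, 50)
    ce = -np.log(probs[np.arange(50), t]).mean()
    assert focal_loss(probs, t, gamma=0.0) == pytest.approx(ce, abs=1e-12)
    # p_y = 0 is clamped, not infinite
    assert np.isfinite(focal_loss(np.array([[0.0, 1.0]]), np.array([0])))


def test_lr_schedule_shape():
    cfg = TrainConfig()
    assert lr_at(14, cfg) == pytest.approx(1e-4)  # end of ramp
    assert lr_at(15, cfg) == pytest.approx(1e-4)  # cosine start: continuous
    assert lr_at(0, cfg) == pytest.approx(1e-4 / 15)
    expected_last = 1e-4 * 0.5 * (1 + np.cos(np.pi * 134 / 135))
    assert lr_at(149, cfg) == pytest.approx(expected_last)
    assert expected_last < 2e-8
    # non-increasing after warmup
    vals = [lr_at(e, cfg) for e in range(15, 150)]
    assert all(a >= b for a, b in zip(vals, vals[1:]))
    with pytest.raises(ValueError):
        lr_at(150, cfg)
    with pytest.raises(ValueError):
        TrainConfig(epochs=10, warmup_epochs=10)


def test_stratified_folds_published_cohort_counts():
    labels = np.repeat(np.arange(5), [217, 118, 93, 41, 41])
    folds = make_folds(labels, k=5, seed=1)
    lgsc_per_fold = np.bincount(folds[labels == 3], minlength=5)
    hgsc_per_fold = np.bincount(folds[labels == 0], minlength=5)
    assert set(lgsc_per_fold) <= {8, 9}
    assert set(hgsc_per_fold) <= {43, 44}
    assert np.array_equal(folds, make_folds(labels, k=5, seed=1))
    assert not np.array_equal(folds, make_folds(labels, k=5, seed=2))
    with pytest.raises(ValueError):
        make_folds(np.array([0, 0, 0, 0, 0, 1, 1, 1, 1]), k=5)  # class of 4


def test_fold_assignment_consistency():
    labels = np.repeat(np.arange(5), [40, 20, 15, 8, 7])
    fa = build_fold_assignment(labels, k=5, seed=4)
    # stage-2 folds only cover non-HGSC slides
    assert (fa.stage2[labels == 0] == -1).all()
    assert (fa.stage2[labels != 0] >= 0).all()
    # each task's folds partition its cohort
    for arr, sel in ((fa.stage1, slice(None)), (fa.flat, slice(None))):
        assert set(arr[sel]) == set(range(5))
    fa2 = build_fold_assignment(labels, k=5, seed=4)
    assert np.array_equal(fa.stage1, fa2.stage1)
    assert np.array_equal(fa.flat, fa2.flat)


def test_well_separated_cohort_reaches_high_balanced_accuracy(small_features):
    """Bags drawn at rho=4 are learnable: meanpool exceeds 0.9 balanced
    accuracy on held-out slides, across three seeds."""
    feats, labels = small_features
    fa = build_fold_assignment(labels, k=5, seed=0)
    tr = np.flatnonzero(fa.flat != 0)
    va = np.flatnonzero(fa.flat == 0)
    spec = AggregatorSpec(name="meanpool", in_dim=64, n_classes=5)
    for seed in range(3):
        cfg = TrainConfig(epochs=10, warmup_epochs=2, patience=10, lr=1e-3, seed=seed)
        _, hist = train_model(feats, labels, spec, cfg, tr, va)
        assert hist["val_metric"].max() >= 0.9


def test_early_stopping_patience(small_features, monkeypatch):
    """With a constant validation metric the loop stops after `patience`
    improvement-free epochs and restores the best-epoch weights."""
    feats, labels = small_features
    fa = build_fold_assignment(labels, k=5, seed=0)
    tr = np.flatnonzero(fa.flat != 0)
    va = np.flatnonzero(fa.flat == 0)
    monkeypatch.setattr(training_mod, "_val_metric", lambda *a, **k: 0.5)
    cfg = TrainConfig(epochs=60, warmup_epochs=2, patience=5, seed=0)
    spec = AggregatorSpec(name="meanpool", in_dim=64, n_classes=5)
    _, hist = train_model(feats, labels, spec, cfg, tr, va)
    assert len(hist) == 6  # epoch 0 is best; stops at epoch 5


def test_best_epoch_weights_are_restored(small_features):
    from slidemil.training import _val_metric

    feats, labels = small_features
    fa = build_fold_assignment(labels, k=5, seed=0)
    tr = np.flatnonzero(fa.flat != 0)
    va = np.flatnonzero(fa.flat == 0)
    cfg = TrainConfig(epochs=6, warmup_epochs=1, patience=6, lr=1e-3, seed=2)
    spec = AggregatorSpec(name="meanpool", in_dim=64, n_classes=5)
    model, hist = train_model(feats, labels, spec, cfg, tr, va)
    returned = _val_metric(model, [feats[i] for i in va], labels[va],
                           "balanced_accuracy")
    assert returned == pytest.approx(hist["val_metric"].max())


def test_train_model_input_validation(small_features):
    feats, labels = small_features
    spec = AggregatorSpec(name="meanpool", in_dim=64, n_classes=5)
    cfg = TrainConfig(epochs=2, warmup_epochs=1, patience=2)
    with pytest.raises(ValueError):
        train_model(feats, labels, spec, cfg, [], [1, 2])
    with pytest.raises(ValueError):
        train_model(feats, labels, spec, cfg, [1, 2, 3], [3, 4])
    single = np.zeros(len(labels), dtype=int)
    with pytest.raises(ValueError):
        train_model(feats, single, spec, cfg, [0, 1, 2], [3, 4])


def test_sensitivity_sweep_shapes(small_features):
    feats, labels = small_features
    binary = (labels == 0).astype(int)
    folds = make_folds(binary, k=2, seed=0)
    spec = AggregatorSpec(name="meanpool", in_dim=64, n_classes=2)
    cfg = TrainConfig(epochs=2, warmup_epochs=1, patience=2, monitor="auroc", seed=0)
    table = sensitivity_sweep([1.0, 2.0], [1.0, 1.5], feats, binary, spec, cfg, folds)
    assert len(table) == 2 * 2 * 2  # grid cells x folds
    assert set(table.columns) == {"gamma", "weight_exponent", "fold", "metric", "value"}
    # a 1x1 grid reduces to plain cross-validation
    one = sensitivity_sweep([2.0], [1.5], feats, binary, spec, cfg, folds)
    assert len(one) == 2
    assert ((one["value"] >= 0) & (one["value"] <= 1)).all()
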