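"""Harness: confusion-matrix metrics vs brute force, schedule, CV, training."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from gppwvgg import (CanopyClassifier, SplitSpec, build_model,
                     confusion_matrix, crossvalidate, evaluate,
                     metrics_from_confusion, split_dataset, train)
from gppwvgg.estimator import images_to_tensor
from gppwvgg.harness import TrainConfig, binary_counts
from gppwvgg.optim import AdamW, StepDecay


# ---------------------------------------------------------------------------
# Metrics vs brute force
# ---------------------------------------------------------------------------

def brute_force_metrics(y_true, y_pred, k):
    """Direct per-class counting from raw (label, prediction) pairs."""
    acc = sum(t == p for t, p in zip(y_true, y_pred)) / len(y_true)
    precision, recall, f1 = [], [], []
    for c in range(k):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        precision.append(prec)
        recall.append(rec)
        f1.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return acc, precision, recall, f1


def test_metrics_agree_with_brute_force_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        k = int(rng.integers(2, 7))
        n = int(rng.integers(5, 40))
        y_true = rng.integers(0, k, size=n)
        y_pred = rng.integers(0, k, size=n)
        report = metrics_from_confusion(confusion_matrix(y_true, y_pred, k))
        acc, prec, rec, f1 = brute_force_metrics(y_true, y_pred, k)
        assert report.accuracy == pytest.approx(acc)
        np.testing.assert_allclose(report.precision, prec, atol=1e-12)
        np.testing.assert_allclose(report.recall, rec, atol=1e-12)
        np.testing.assert_allclose(report.f1, f1, atol=1e-12)


def test_metrics_cross_checked_against_sklearn(rng):
    y_true = rng.integers(0, 4, size=200)
    y_pred = rng.integers(0, 4, size=200)
    report = metrics_from_confusion(confusion_matrix(y_true, y_pred, 4))
    p, r, f, _ = precision_recall_fscore_support(
        y_true, y_pred, average="macro", zero_division=0)
    assert report.macro_precision == pytest.approx(p)
    assert report.macro_recall == pytest.approx(r)
    assert report.macro_f1 == pytest.approx(f)


def test_binary_counts_toy_example():
    # TP=50, TN=40, FP=5, FN=5 -> ACC=0.90, P=R=F1=50/55
    cm = np.array([[50, 5], [5, 40]])
    tp, fp, fn, tn = binary_counts(cm)
    assert (tp[0], fp[0], fn[0], tn[0]) == (50, 5, 5, 40)
    report = metrics_from_confusion(cm)
    assert report.accuracy == pytest.approx(0.90)
    assert report.precision[0] == pytest.approx(50 / 55)
    assert report.recall[0] == pytest.approx(50 / 55)
    assert report.f1[0] == pytest.approx(50 / 55)


def test_three_class_toy_matrix():
    cm = np.array([[8, 1, 1], [0, 9, 1], [2, 0, 8]])
    report = metrics_from_confusion(cm)
    assert report.accuracy == pytest.approx(25 / 30)
    assert report.precision[0] == pytest.approx(8 / 10)
    assert report.recall[0] == pytest.approx(8 / 10)
    assert cm.sum() == 30  # conservation: every evaluated sample counted once


def test_perfect_predictions_score_one():
    report = metrics_from_confusion(np.diag([7, 3, 5]))
    assert report.accuracy == report.macro_precision == report.macro_recall \
        == report.macro_f1 == 1.0


def test_f1_zero_when_precision_plus_recall_zero():
    # class 0 never predicted and never present -> P = R = 0 -> F1 := 0
    cm = np.array([[0, 0], [5, 5]])
    report = metrics_from_confusion(cm)
    assert report.precision[0] == report.recall[0] == report.f1[0] == 0.0


def test_macro_f1_invariant_under_relabeling(rng):
    cm = rng.integers(0, 20, size=(5, 5))
    cm[0, 0] += 1  # non-empty
    perm = rng.permutation(5)
    base = metrics_from_confusion(cm).macro_f1
    permuted = metrics_from_confusion(cm[np.ix_(perm, perm)]).macro_f1
    assert permuted == pytest.approx(base)


def test_confusion_matrix_validates_labels():
    with pytest.raises(ValueError):
        confusion_matrix([0, 1], [0, 5], num_classes=3)


# ---------------------------------------------------------------------------
# Schedule and training loop
# ---------------------------------------------------------------------------

def test_learning_rate_halves_on_decay_event():
    model = build_model("g_ppw_vgg11", num_classes=6, input_size=32)
    opt = AdamW(model.parameters(), lr=0.005)
    sched = StepDecay(opt, factor=0.5, every=30)
    for _ in range(29):
        sched.step_epoch()
    assert opt.lr == 0.005
    sched.step_epoch()
    assert opt.lr == pytest.approx(0.0025)


def test_training_is_seed_deterministic(tiny_train_images):
    X, y = tiny_train_images
    Xt = images_to_tensor(X[:32], 32)
    losses = []
    for _ in range(2):
        model = build_model("g_ppw_vgg11", seed=1, num_classes=6, input_size=32)
        cfg = TrainConfig(batch_size=16, epochs=1, seed=1)
        log = train(model, Xt, y[:32], cfg)
        losses.append(log.epoch_losses[0])
    assert round(losses[0], 6) == round(losses[1], 6)


def test_train_rejects_degenerate_datasets():
    model = build_model("g_ppw_vgg11", num_classes=6, input_size=32)
    cfg = TrainConfig(epochs=1)
    with pytest.raises(ValueError, match="empty"):
        train(model, np.zeros((0, 3, 32, 32), np.float32), np.zeros(0, int), cfg)
    with pytest.raises(ValueError, match="two classes"):
        train(model, np.zeros((4, 3, 32, 32), np.float32),
              np.zeros(4, int), cfg)


def test_train_raises_on_non_finite_loss(tiny_train_images):
    X, y = tiny_train_images
    Xt = images_to_tensor(X[:16], 32)
    model = build_model("g_ppw_vgg11", num_classes=6, input_size=32)
    # poison the final (post-ReLU) projection so the loss itself goes NaN
    list(model.head.parameters())[-1].data[:] = np.nan
    with pytest.raises(FloatingPointError):
        train(model, Xt, y[:16], TrainConfig(epochs=1))


def test_evaluate_rejects_labels_outside_head(tiny_train_images):
    X, y = tiny_train_images
    Xt = images_to_tensor(X[:8], 32)
    model = build_model("g_ppw_vgg11", num_classes=4, input_size=32)
    with pytest.raises(ValueError, match="head"):
        evaluate(model, Xt, np.full(8, 5))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def test_crossvalidate_mean_equals_fold_mean(easy_dataset):
    X, y = easy_dataset
    sub = np.concatenate([np.where(y == c)[0][:8] for c in range(6)])
    Xt = images_to_tensor(X[sub], 32)
    cfg = TrainConfig.desk(epochs=2, batch_size=16, seed=0)
    result = crossvalidate(
        lambda: build_model("g_ppw_vgg11", seed=0, num_classes=6, input_size=32),
        Xt, y[sub], k=3, cfg=cfg, seed=0)
    accs = [r.accuracy for r in result.fold_reports]
    assert result.mean_accuracy == pytest.approx(np.mean(accs))
    assert len(accs) == 3


def test_two_fold_cv_on_separable_synthetic_data(easy_dataset):
    X, y = easy_dataset
    Xt = images_to_tensor(X, 32)
    cfg = TrainConfig.desk(epochs=10, batch_size=32, seed=0)
    result = crossvalidate(
        lambda: build_model("g_ppw_vgg11", seed=0, num_classes=6, input_size=32),
        Xt, y, k=2, cfg=cfg, seed=0)
    assert result.mean_accuracy > 0.9


def test_crossvalidate_requires_k_at_least_two(easy_dataset):
    X, y = easy_dataset
    with pytest.raises(ValueError):
        crossvalidate(lambda: None, X[:12], y[:12], k=1)
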