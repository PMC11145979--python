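"""Training and evaluation harness.

Training follows the published recipe: AdamW, cross-entropy loss, initial
learning rate 0.005 halved on a fixed epoch cadence, batch size 112 for 120
epochs (:meth:`TrainConfig.table4`).  A desk-scale profile
(:meth:`TrainConfig.desk`) shrinks batch/epochs for CPU-sized experiments;
the schedule and optimiser are identical.

Evaluation reduces argmax predictions to a K x K confusion matrix and derives
accuracy, per-class and macro precision / recall / F1 by one-vs-rest
reduction, plus a macro one-vs-rest AUC from the softmax scores.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .architectures import Model
from .datapipe import SplitSpec, split_dataset
from .layers import CrossEntropyLoss, Layer, softmax
from .optim import AdamW, StepDecay


@dataclass
class TrainConfig:
    """Optimiser / schedule settings (defaults follow the published recipe)."""

    lr: float = 0.005
    lr_decay: float = 0.5
    decay_every: int = 30          # epochs between x lr_decay steps
    batch_size: int = 112
    epochs: int = 120
    weight_decay: float = 0.01
    max_steps: int | None = None   # optional hard cap on optimiser steps
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("decay factor must be in (0, 1]")

    @classmethod
    def table4(cls, **overrides) -> "TrainConfig":
        """The paper-faithful profile (batch 112, 120 epochs, lr 0.005)."""
        return cls(**overrides)

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        """CPU desk-scale profile: same optimiser/schedule, smaller footprint."""
        base = dict(batch_size=32, epochs=20, decay_every=8)
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainLog:
    epoch_losses: list[float] = field(default_factory=list)
    step_losses: list[float] = field(default_factory=list)
    epoch_accs: list[float] = field(default_factory=list)
    val_accs: list[float] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)
    best_val_acc: float = float("nan")
    best_state: dict | None = None
    steps: int = 0


def train(model: Layer, X: np.ndarray, y: np.ndarray, cfg: TrainConfig,
          X_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
          verbose: bool = False) -> TrainLog:
    """Fit ``model`` on (X, y); X is (n, 3, H, W) float32, y integer labels.

    Returns the per-epoch loss/accuracy log; when a validation set is given,
    the best state dict (by validation accuracy) is retained in the log.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    if len(X) == 0:
        raise ValueError("cannot train on an empty dataset")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two classes")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X/y length mismatch")

    rng = np.random.default_rng(cfg.seed)
    loss_fn = CrossEntropyLoss()
    optimizer = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    schedule = StepDecay(optimizer, factor=cfg.lr_decay, every=cfg.decay_every)
    log = TrainLog()
    model.train()

    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(X))
        epoch_losses = []
        correct = 0
        for start in range(0, len(X), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            logits = model.forward(xb)
            loss = loss_fn.forward(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at step {log.steps}")
            optimizer.zero_grad()
            model.backward(loss_fn.backward())
            optimizer.step()
            epoch_losses.append(loss)
            log.step_losses.append(loss)
            correct += int((logits.argmax(axis=1) == yb).sum())
            log.steps += 1
            if cfg.max_steps is not None and log.steps >= cfg.max_steps:
                break
        log.epoch_losses.append(float(np.mean(epoch_losses)))
        log.epoch_accs.append(correct / len(X))
        log.lrs.append(optimizer.lr)
        if X_val is not None:
            _, report = evaluate(model, X_val, y_val)
            model.train()
            log.val_accs.append(report.accuracy)
            if not (log.best_val_acc >= report.accuracy):  # NaN-safe
                log.best_val_acc = report.accuracy
                if isinstance(model, Model):
                    log.best_state = copy.deepcopy(model.state_dict())
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs} "
                  f"loss={log.epoch_losses[-1]:.4f} acc={log.epoch_accs[-1]:.4f} "
                  f"lr={optimizer.lr:.5f}")
        schedule.step_epoch()
        if cfg.max_steps is not None and log.steps >= cfg.max_steps:
            break
    return log


# ---------------------------------------------------------------------------
# Confusion matrix and metrics
# ---------------------------------------------------------------------------

def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     num_classes: int) -> np.ndarray:
    """K x K count matrix; rows are true classes, columns predictions."""
    y_true = np.asarray(y_true, dtype=np.intp)
    y_pred = np.asarray(y_pred, dtype=np.intp)
    if y_true.shape != y_pred.shape:
        raise ValueError("label/prediction length mismatch")
    if y_true.size and (y_true.max() >= num_classes or y_pred.max() >= num_classes
                        or y_true.min() < 0 or y_pred.min() < 0):
        raise ValueError(f"labels outside [0, {num_classes})")
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def binary_counts(cm: np.ndarray):
    """One-vs-rest (TP, FP, FN, TN) per class from a confusion matrix."""
    total = cm.sum()
    tp = np.diag(cm).astype(np.int64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn
    return tp, fp, fn, tn


@dataclass
class MetricsReport:
    """Accuracy / precision / recall / F1 (fractions in [0, 1]) and macro AUC."""

    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    per_class_accuracy: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_auc: float | None = None

    def as_percent(self) -> dict:
        d = {
            "ACC": round(100 * self.accuracy, 2),
            "precision": round(100 * self.macro_precision, 2),
            "recall": round(100 * self.macro_recall, 2),
            "F1": round(100 * self.macro_f1, 2),
        }
        if self.macro_auc is not None:
            d["AUC"] = round(100 * self.macro_auc, 2)
        return d


def _safe_div(a, b):
    out = np.zeros_like(a, dtype=float)
    np.divide(a, b, out=out, where=b > 0)
    return out


def metrics_from_confusion(cm: np.ndarray, macro_auc: float | None = None
                           ) -> MetricsReport:
    """Accuracy, per-class and macro P/R/F1 by one-vs-rest reduction.

    F1 is defined as 0 whenever P + R = 0 (the harmonic mean is 0/0 there).
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = binary_counts(cm)
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    per_class_acc = (tp + tn) / total
    return MetricsReport(
        accuracy=float(np.trace(cm) / total),
        precision=precision, recall=recall, f1=f1,
        per_class_accuracy=per_class_acc,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        macro_auc=macro_auc,
    )


def predict_scores(model: Layer, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Softmax class scores in eval mode, batched."""
    model.eval()
    out = []
    for start in range(0, len(X), batch_size):
        logits = model.forward(np.asarray(X[start : start + batch_size],
                                          dtype=np.float32))
        out.append(softmax(logits))
    return np.concatenate(out, axis=0)


def evaluate(model: Layer, X: np.ndarray, y: np.ndarray,
             batch_size: int = 64) -> tuple[np.ndarray, MetricsReport]:
    """Confusion matrix + metrics report for argmax predictions on (X, y)."""
    y = np.asarray(y)
    scores = predict_scores(model, X, batch_size)
    num_classes = scores.shape[1]
    if y.size and y.max() >= num_classes:
        raise ValueError(
            f"label {int(y.max())} outside the model's {num_classes}-class head")
    preds = scores.argmax(axis=1)  # ties resolve to the lowest class index
    cm = confusion_matrix(y, preds, num_classes)
    auc = None
    if len(np.unique(y)) == num_classes:
        auc = float(roc_auc_score(y, scores, multi_class="ovr", average="macro"))
    return cm, metrics_from_confusion(cm, macro_auc=auc)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_reports: list[MetricsReport]
    mean_accuracy: float
    sd_accuracy: float
    mean_macro_f1: float
    sd_macro_f1: float


def crossvalidate(build_fn, X: np.ndarray, y: np.ndarray, k: int = 3,
                  cfg: TrainConfig | None = None, seed: int = 0,
                  verbose: bool = False) -> CVResult:
    """Leave-one-fold-out k-fold CV; ``build_fn()`` returns a fresh model."""
    if k < 2:
        raise ValueError("cross-validation requires k >= 2")
    cfg = cfg or TrainConfig.desk()
    folds = split_dataset(y, SplitSpec(k=k, seed=seed))
    reports = []
    for i, (train_idx, test_idx) in enumerate(folds):
        model = build_fn()
        train(model, X[train_idx], y[train_idx], cfg)
        _, report = evaluate(model, X[test_idx], y[test_idx])
        reports.append(report)
        if verbose:
            print(f"fold {i + 1}/{k}: ACC={report.accuracy:.4f}")
    accs = np.array([r.accuracy for r in reports])
    f1s = np.array([r.macro_f1 for r in reports])
    return CVResult(reports, float(accs.mean()), float(accs.std(ddof=0)),
                    float(f1s.mean()), float(f1s.std(ddof=0)))
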