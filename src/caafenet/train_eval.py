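"""Training loop, classification metrics and the ablation harness.

Training follows the published recipe: SGD with learning rate 1e-3, weight
decay 1e-5, momentum 0.7, batch size 16, cross-entropy over the LogSoftmax
head (i.e. the mean negative selected log-probability), 40 epochs, with
rotation/flip/photometric augmentation on the training split only.  The
checkpoint with the best validation accuracy is retained.

Metrics are the usual confusion-matrix family -- accuracy, precision,
recall and their harmonic mean F1, reported as percentages -- plus AUC via
the Mann-Whitney rank statistic (tied scores receive average ranks), which
equals trapezoidal integration of the ROC curve.  The positive class
defaults to the majority ("poor prognosis") class.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import AugmentConfig, augment_slice, read_slice_png
from .network import build_variant, count_parameters, CAAFEResNet
from .nn.optim import SGD

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "poor"  # majority class; configurable per call


@dataclass
class TrainConfig:
    lr: float = 0.001
    weight_decay: float = 0.00001
    momentum: float = 0.7
    batch_size: int = 16
    epochs: int = 40
    augment: bool = True
    augment_config: AugmentConfig = field(default_factory=AugmentConfig)
    stop_at_val_accuracy: float | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("lr", "weight_decay", "momentum", "batch_size", "epochs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float            # percent
    precision: float           # percent
    recall: float              # percent
    f1: float                  # percent
    confusion: ConfusionCounts
    auc: float | None = None   # fraction in [0, 1]
    degenerate: bool = False   # a zero denominator was replaced by 0


def nll_from_log_probs(log_probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true labels."""
    labels = np.asarray(labels)
    n, k = log_probs.shape
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(
            f"labels must lie in [0, {k}), got range "
            f"[{labels.min()}, {labels.max()}]")
    return float(-log_probs[np.arange(n), labels].mean())


def nll_gradient(log_probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """d(mean NLL)/d(log_probs): -1/n at the true label, 0 elsewhere."""
    n = log_probs.shape[0]
    grad = np.zeros_like(log_probs)
    grad[np.arange(n), np.asarray(labels)] = -1.0 / n
    return grad


def confusion_from_predictions(predicted, truth,
                               positive_class=1) -> ConfusionCounts:
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} vs {truth.shape}")
    pos_pred = predicted == positive_class
    pos_true = truth == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_pred & pos_true)),
        tn=int(np.sum(~pos_pred & ~pos_true)),
        fp=int(np.sum(pos_pred & ~pos_true)),
        fn=int(np.sum(~pos_pred & pos_true)),
    )


def f1_score(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    if precision_pct + recall_pct == 0:
        return 0.0
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    degenerate = False
    accuracy = 100.0 * (c.tp + c.tn) / c.total
    if c.tp + c.fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = 100.0 * c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = 100.0 * c.tp / (c.tp + c.fn)
    return MetricsReport(accuracy=accuracy, precision=precision,
                         recall=recall, f1=f1_score(precision, recall),
                         confusion=c, degenerate=degenerate)


def roc_auc(scores, labels) -> float:
    """AUC via the rank statistic; ties get average ranks."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "AUC is undefined when only one class is present "
            f"(positives={n_pos}, negatives={n_neg})")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def load_split_arrays(manifest: pd.DataFrame, split: str,
                      positive_label: str = POSITIVE_LABEL):
    """Images (N,1,H,W) float32 and 0/1 labels for one manifest split."""
    rows = manifest[manifest["split"] == split]
    if rows.empty:
        raise ValueError(f"manifest has no rows in split {split!r}")
    images = np.stack([
        read_slice_png(p)[None].astype(np.float32) for p in rows["path"]
    ])
    labels = (rows["label"] == positive_label).to_numpy().astype(np.int64)
    return images, labels


def predict_log_probs(model: CAAFEResNet, images: np.ndarray,
                      batch_size: int = 16) -> np.ndarray:
    out = [model.forward(images[i:i + batch_size], training=False)
           for i in range(0, len(images), batch_size)]
    return np.concatenate(out, axis=0)


def evaluate(model: CAAFEResNet, images: np.ndarray,
             labels: np.ndarray, batch_size: int = 16) -> MetricsReport:
    logp = predict_log_probs(model, images, batch_size)
    pred = logp.argmax(axis=1)
    report = compute_metrics(confusion_from_predictions(pred, labels))
    scores = np.exp(logp[:, 1])
    if len(np.unique(labels)) == 2:
        report.auc = roc_auc(scores, labels)
    return report


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = -np.inf
    best_state: dict | None = None

    def __len__(self):
        return len(self.train_loss)


def train_model(model: CAAFEResNet, train_images, train_labels,
                val_images, val_labels, cfg: TrainConfig) -> TrainHistory:
    """SGD training on in-memory arrays; returns the per-epoch history.

    The best-validation-accuracy state is kept in ``history.best_state``
    and restored into the model on return.
    """
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("training and validation splits must be non-empty")
    opt = SGD(model, lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_images))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = train_images[idx]
            if cfg.augment:
                batch = np.stack([
                    augment_slice(img[0], int(rng.integers(2**31)),
                                  cfg.augment_config)[None].astype(np.float32)
                    for img in batch
                ])
            labels = train_labels[idx]
            opt.zero_grad()
            logp = model.forward(batch, training=True)
            loss = nll_from_log_probs(logp, labels)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss {loss} at epoch {epoch}")
            model.backward(nll_gradient(logp, labels))
            opt.step()
            losses.append(loss)
        val_report = evaluate(model, val_images, val_labels, cfg.batch_size)
        history.train_loss.append(float(np.mean(losses)))
        history.val_accuracy.append(val_report.accuracy)
        logger.info("epoch %d: train loss %.4f, val accuracy %.2f%%",
                    epoch, history.train_loss[-1], val_report.accuracy)
        if val_report.accuracy > history.best_val_accuracy:
            history.best_val_accuracy = val_report.accuracy
            history.best_epoch = epoch
            history.best_state = copy.deepcopy(model.state_dict())
        if (cfg.stop_at_val_accuracy is not None
                and history.best_val_accuracy >= cfg.stop_at_val_accuracy):
            break
    if history.best_state is not None:
        model.load_state_dict(history.best_state)
    return history


ABLATION_COLUMNS = ["Model", "Parameters", "Accuracy (%)", "Precision (%)",
                    "Recall (%)", "F1 score (%)", "AUC"]

VARIANT_DISPLAY = {
    "resnet18*": "ResNet18*",
    "+B1": "ResNet18* + CAAFEB1",
    "+B1B2": "ResNet18* + CAAFEB1 + CAAFEB2",
    "+B1B2B3": "ResNet18* + CAAFEB1 + CAAFEB2 + CAAFEB3",
    "full": "CAAFE-ResNet18*",
    "se": "ResNet18* + SE",
    "cbam": "ResNet18* + CBAM",
}


def run_ablation(variants, data, train_cfg: TrainConfig,
                 model_seed: int = 0) -> pd.DataFrame:
    """Train each requested variant on the same arrays and tabulate metrics.

    ``data`` is a dict with keys train/val/test, each an (images, labels)
    pair (e.g. from :func:`load_split_arrays`).
    """
    rows = []
    for name in variants:
        model = build_variant(name, seed=model_seed)
        train_model(model, *data["train"], *data["val"], train_cfg)
        report = evaluate(model, *data["test"], train_cfg.batch_size)
        rows.append({
            "Model": VARIANT_DISPLAY.get(name, name),
            "Parameters": count_parameters(model),
            "Accuracy (%)": round(report.accuracy, 2),
            "Precision (%)": round(report.precision, 2),
            "Recall (%)": round(report.recall, 2),
            "F1 score (%)": round(report.f1, 2),
            "AUC": None if report.auc is None else round(report.auc, 4),
        })
    return pd.DataFrame(rows, columns=ABLATION_COLUMNS)


def ablation_markdown(table: pd.DataFrame) -> str:
    header = "| " + " | ".join(table.columns) + " |"
    sep = "| " + " | ".join("---" for _ in table.columns) + " |"
    lines = [header, sep]
    for _, row in table.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines)
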