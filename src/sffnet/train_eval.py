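"""Lesion-grouped splitting, the training protocol, and evaluation metrics.

Splitting is stratified by class and grouped by lesion: every slice of a
lesion inherits the lesion's split, so no tumor contributes to both the
training and the held-out set (slices of one lesion are strongly
correlated and would otherwise leak).

Training follows a fixed protocol: momentum SGD on 2-class cross-entropy,
a step learning-rate schedule (multiplicative decay every fixed number of
epochs), and checkpoint selection by best validation accuracy with ties
broken toward the earlier epoch.

Metrics are computed per slice: per-class precision/recall/F1 from the
confusion matrix (rows = truth, columns = prediction), overall accuracy,
and ROC-AUC by explicit threshold sweep with trapezoidal integration —
which equals the Mann-Whitney pairwise-concordance statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .model import SFFNet

__all__ = [
    "CLASS_ORDER",
    "SplitAssignment",
    "TrainConfig",
    "MetricsReport",
    "split_lesions",
    "lr_at_epoch",
    "train",
    "TrainResult",
    "evaluate",
    "report_from_confusion",
    "roc_auc",
    "embed_2d",
    "majority_vote_report",
]

CLASS_ORDER = ("HCC", "MF-ICC")
POSITIVE_CLASS = "MF-ICC"  # headline ROC/AUC treats MF-ICC as positive
SPLITS = ("train", "validation", "test")


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    assignment: dict[str, str]  # lesion_id -> split name
    ratios: tuple[float, float, float]
    seed: int

    def lesions_for(self, split: str) -> list[str]:
        return sorted(k for k, v in self.assignment.items() if v == split)

    def split_of(self, lesion_id: str) -> str:
        return self.assignment[lesion_id]


def _largest_remainder(n: int, ratios: tuple[float, float, float]) -> list[int]:
    quotas = [n * r for r in ratios]
    base = [int(np.floor(q)) for q in quotas]
    rem = n - sum(base)
    # assign leftovers by largest fractional part; ties favor earlier splits
    order = sorted(range(3), key=lambda i: (-(quotas[i] - base[i]), i))
    for i in order[:rem]:
        base[i] += 1
    return base


def split_lesions(
    lesion_table: dict[str, str] | pd.DataFrame,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Stratified, lesion-level 3-way split.

    ``lesion_table`` maps lesion_id -> class label (or is a DataFrame with
    ``lesion_id``/``class_label`` columns).  Per class, counts follow the
    ratios by floor allocation with largest-remainder rounding; the draw is
    a seeded shuffle, so a fixed seed reproduces the assignment exactly.
    """
    if isinstance(lesion_table, pd.DataFrame):
        table = dict(
            zip(lesion_table["lesion_id"].astype(str), lesion_table["class_label"])
        )
    else:
        table = dict(lesion_table)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    by_class: dict[str, list[str]] = {}
    for lesion, label in table.items():
        by_class.setdefault(label, []).append(lesion)
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for label in sorted(by_class):
        lesions = sorted(by_class[label])
        if len(lesions) < 3:
            raise ValueError(
                f"class {label!r} has only {len(lesions)} lesions; need >= 3"
            )
        rng.shuffle(lesions)
        counts = _largest_remainder(len(lesions), ratios)
        idx = 0
        for split, cnt in zip(SPLITS, counts):
            for lesion in lesions[idx : idx + cnt]:
                assignment[lesion] = split
            idx += cnt
    return SplitAssignment(assignment=assignment, ratios=tuple(ratios), seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimization protocol; defaults follow the published recipe."""

    initial_lr: float = 0.001
    lr_decay_factor: float = 0.1
    lr_step_epochs: int = 30
    batch_size: int = 16
    epochs: int = 100
    momentum: float = 0.9
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.initial_lr, self.lr_decay_factor, self.batch_size) <= 0:
            raise ValueError("learning-rate and batch parameters must be positive")
        if self.epochs < 1 or self.lr_step_epochs < 1:
            raise ValueError("epochs and lr_step_epochs must be >= 1")


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Step schedule: initial_lr * decay^floor(epoch / step)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.initial_lr * config.lr_decay_factor ** (epoch // config.lr_step_epochs)


@dataclass
class TrainResult:
    history: pd.DataFrame  # epoch, lr, train_loss, train_accuracy, val_accuracy
    best_epoch: int
    best_val_accuracy: float
    best_state: dict = field(repr=False, default_factory=dict)


def train(
    model: SFFNet,
    datasets: dict[str, tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
) -> TrainResult:
    """Train with momentum SGD / cross-entropy; keep the best-validation weights.

    ``datasets`` maps ``"train"`` and ``"validation"`` to ``(images, labels)``
    with images shaped (N, C, S, S) in [0, 1] and integer labels indexing
    :data:`CLASS_ORDER`.  The best checkpoint (highest validation accuracy,
    earliest epoch on ties) is restored into ``model`` before returning.
    """
    for split in ("train", "validation"):
        if split not in datasets or len(datasets[split][0]) == 0:
            raise ValueError(f"empty or missing {split!r} split")
    x_train, y_train = datasets["train"]
    x_val, y_val = datasets["validation"]
    x_train = np.asarray(x_train, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=np.int64)
    rng = np.random.default_rng(config.seed)
    opt = nn.SGD(
        model.parameters(),
        lr=config.initial_lr,
        momentum=config.momentum,
        weight_decay=config.weight_decay,
    )
    n = len(x_train)
    records = []
    best_epoch, best_acc, best_state = -1, -np.inf, None
    for epoch in range(config.epochs):
        opt.lr = lr_at_epoch(epoch, config)
        model.train()
        order = rng.permutation(n)
        losses = []
        correct = 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb = nn.Tensor(x_train[idx])
            logits = model(xb)
            loss = nn.cross_entropy(logits, y_train[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y_train[idx]).sum())
        train_loss = float(np.mean(losses))
        if not np.isfinite(train_loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        val_acc = _accuracy(model, x_val, y_val, config.batch_size)
        records.append(
            {
                "epoch": epoch,
                "lr": opt.lr,
                "train_loss": train_loss,
                "train_accuracy": correct / n,
                "val_accuracy": val_acc,
            }
        )
        if val_acc > best_acc:
            best_epoch, best_acc = epoch, val_acc
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return TrainResult(
        history=pd.DataFrame(records),
        best_epoch=best_epoch,
        best_val_accuracy=float(best_acc),
        best_state=best_state,
    )


def _accuracy(model: SFFNet, x: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    probs = model.predict_proba(np.asarray(x, dtype=np.float32), batch_size)
    return float((probs.argmax(axis=1) == np.asarray(y)).mean())


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-class rates, overall accuracy, AUC and the confusion matrix."""

    class_order: tuple[str, str]
    confusion: np.ndarray  # rows = truth, cols = prediction
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    accuracy: float
    auc: dict[str, float] = field(default_factory=dict)
    macro_auc: float = float("nan")
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "confusion": self.confusion.astype(int).tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "macro_auc": self.macro_auc,
            "warnings": self.warnings,
        }


def report_from_confusion(
    confusion: np.ndarray, class_order: tuple[str, str] = CLASS_ORDER
) -> MetricsReport:
    """Precision/recall/F1 per class and accuracy from a confusion matrix.

    Zero denominators yield a rate of 0 with a recorded warning rather than
    an exception (the convention for degenerate predictors).
    """
    cm = np.asarray(confusion, dtype=np.int64)
    if cm.shape != (len(class_order), len(class_order)):
        raise ValueError(f"confusion matrix must be {len(class_order)}-square")
    notes: list[str] = []
    precision, recall, f1 = {}, {}, {}
    for i, label in enumerate(class_order):
        tp = cm[i, i]
        pred_pos = cm[:, i].sum()
        true_pos = cm[i, :].sum()
        if pred_pos == 0:
            notes.append(f"no predictions for class {label}; precision set to 0")
        if true_pos == 0:
            notes.append(f"no true items of class {label}; recall set to 0")
        p = tp / pred_pos if pred_pos else 0.0
        r = tp / true_pos if true_pos else 0.0
        precision[label] = float(p)
        recall[label] = float(r)
        f1[label] = float(2 * p * r / (p + r)) if (p + r) > 0 else 0.0
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else 0.0
    for note in notes:
        warnings.warn(note, stacklevel=2)
    return MetricsReport(
        class_order=tuple(class_order),
        confusion=cm,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        warnings=notes,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC by threshold sweep and trapezoidal AUC.

    ``labels`` are 1 for the positive class, 0 otherwise; ``scores`` are the
    positive-class scores.  Returns ``(fpr, tpr, auc)`` with the curve
    anchored at (0, 0).  Raises when only one class is present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(np.int64)
    pos = int(labels.sum())
    neg = int(len(labels) - pos)
    if pos == 0 or neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    # thresholds at distinct score values only (ties move as one block)
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = (distinct + 1) - tp
    tpr = np.r_[0.0, tp / pos]
    fpr = np.r_[0.0, fp / neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def evaluate(
    model: SFFNet,
    images: np.ndarray,
    labels: np.ndarray,
    class_order: tuple[str, str] = CLASS_ORDER,
    batch_size: int = 16,
) -> MetricsReport:
    """Full per-slice metrics for a held-out set.

    Predictions are the argmax of the logits; AUC scores are softmax
    probabilities, computed per class by treating each class as positive in
    turn (the macro average equals either class's AUC in the binary case).
    A single-class test set yields NaN AUCs with a warning.
    """
    labels = np.asarray(labels, dtype=np.int64)
    probs = model.predict_proba(np.asarray(images, dtype=np.float32), batch_size)
    preds = probs.argmax(axis=1)
    k = len(class_order)
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (labels, preds), 1)
    report = report_from_confusion(cm, class_order)
    aucs = {}
    for i, label in enumerate(class_order):
        try:
            _, _, aucs[label] = roc_auc(probs[:, i], (labels == i).astype(int))
        except ValueError:
            aucs[label] = float("nan")
            msg = f"AUC undefined for class {label}: only one class present"
            report.warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
    report.auc = aucs
    vals = [v for v in aucs.values() if np.isfinite(v)]
    report.macro_auc = float(np.mean(vals)) if vals else float("nan")
    return report


def majority_vote_report(
    labels: np.ndarray,
    preds: np.ndarray,
    lesion_ids: list[str],
    class_order: tuple[str, str] = CLASS_ORDER,
) -> MetricsReport:
    """Lesion-level metrics by majority vote over each lesion's slices.

    Offered as a clearly separated extra; the headline metrics are per
    slice.  Vote ties go to the first class in ``class_order``.
    """
    df = pd.DataFrame({"lesion": lesion_ids, "y": labels, "p": preds})
    rows = df.groupby("lesion").agg(
        y=("y", "first"),
        p=("p", lambda v: np.argmax(np.bincount(v, minlength=len(class_order)))),
    )
    k = len(class_order)
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (rows["y"].to_numpy(), rows["p"].to_numpy()), 1)
    return report_from_confusion(cm, class_order)


# ---------------------------------------------------------------------------
# qualitative embedding
# ---------------------------------------------------------------------------

def embed_2d(features: np.ndarray, seed: int = 0) -> np.ndarray:
    """t-SNE scatter coordinates for qualitative inspection (deterministic)."""
    features = np.asarray(features, dtype=np.float64)
    n = len(features)
    if n < 5:
        raise ValueError(f"need at least 5 items to embed, got {n}")
    from sklearn.manifold import TSNE

    perplexity = float(min(30.0, max(2.0, (n - 1) / 3.0)))
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        max_iter=500,
    )
    return tsne.fit_transform(features)
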