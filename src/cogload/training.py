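"""Subject-specific training protocol and evaluation surface.

The protocol: stratified seeded 70/15/15 split of one subject's
session matrices, batch size 64, up to 1000 epochs with early stopping
on validation loss (best-weights restore) and a step-down learning-rate
schedule. Evaluation reports accuracy, per-class precision/recall/F1,
the 3x3 confusion matrix and one-vs-rest ROC AUC per class, plus a
cross-subject mean +/- SD summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

from cogload import nn
from cogload.containers import CLASS_LABELS, EvalReport
from cogload.errors import InvalidArgumentError
from cogload.models import build_model, model_spec, prepare_inputs


@dataclass
class TrainConfig:
    """Training protocol parameters (defaults mirror the study protocol)."""

    split_ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    batch_size: int = 64
    max_epochs: int = 1000
    early_stop_patience: int = 50
    lr: float = 1e-3
    lr_patience: int = 20
    lr_factor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise InvalidArgumentError("split ratios must sum to 1")
        if self.batch_size < 1:
            raise InvalidArgumentError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise InvalidArgumentError("max_epochs must be >= 1")


def split_sizes(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    """Train gets floor(r0*n); validation/test split the rest evenly,
    validation taking the extra item when the remainder is odd."""
    n_train = int(np.floor(ratios[0] * n))
    rem = n - n_train
    n_val = (rem + 1) // 2
    return n_train, n_val, rem - n_val


def split_dataset(
    labels: np.ndarray | list,
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified seeded 70/15/15 index split.

    Items of each class are shuffled into per-class pools and
    interleaved round-robin, then the interleaved order is cut at the
    global boundaries from :func:`split_sizes`, so strata stay balanced
    and the split is an exhaustive disjoint partition. Returns
    (train_idx, val_idx, test_idx).
    """
    labels = np.asarray(labels)
    n = labels.size
    classes = np.unique(labels)
    if n < classes.size or n < 3:
        raise InvalidArgumentError("need at least one item per class and >= 3 items")
    rng = np.random.default_rng(seed)
    pools = []
    for c in rng.permutation(classes):
        idx = np.flatnonzero(labels == c)
        pools.append(list(rng.permutation(idx)))
    interleaved = []
    while any(pools):
        for pool in pools:
            if pool:
                interleaved.append(pool.pop())
    order = np.array(interleaved)
    n_train, n_val, _n_test = split_sizes(n, ratios)
    return (
        order[:n_train],
        order[n_train : n_train + n_val],
        order[n_train + n_val :],
    )


def scale_features(
    train: np.ndarray, *others: np.ndarray, metric: str = "MI"
) -> tuple[np.ndarray, ...]:
    """Scale matrices for training: MI is divided by the training-set
    maximum; PLV/dPTE are already in [0, 1] and pass through."""
    if metric.upper() != "MI":
        return (train, *others)
    scale = float(np.max(train))
    if scale <= 0:
        scale = 1.0
    return tuple(a / scale for a in (train, *others))


def encode_labels(labels, class_names: tuple[str, ...] = CLASS_LABELS) -> np.ndarray:
    """Map class labels to one-hot rows in canonical class order."""
    index = {c: k for k, c in enumerate(class_names)}
    y = np.zeros((len(labels), len(class_names)))
    for row, lab in enumerate(labels):
        y[row, index[lab]] = 1.0
    return y


def train_model(
    model: nn.Network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
) -> dict[str, list[float]]:
    """Mini-batch Adam training with early stopping and LR step-down.

    Stops at max_epochs or when validation loss has not improved for
    early_stop_patience epochs (patience 0 stops after the first
    non-improving epoch); the learning rate is halved after lr_patience
    non-improving epochs; best-validation-loss weights are restored.
    Returns the per-epoch history.
    """
    if len(x_train) == 0 or len(x_val) == 0:
        raise InvalidArgumentError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(lr=config.lr)
    history: dict[str, list[float]] = {
        "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": [], "lr": [],
    }
    best_val = np.inf
    best_weights = model.get_weights()
    since_improve = 0

    def _eval(x, y):
        probs = model.predict_proba(x)
        eps = 1e-12
        loss = float(-np.mean(np.sum(y * np.log(probs + eps), axis=1)))
        acc = float(np.mean(probs.argmax(axis=1) == y.argmax(axis=1)))
        return loss, acc

    n = len(x_train)
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            loss = model.loss_and_grads(x_train[batch], y_train[batch])
            opt.step(model)
            epoch_loss += loss * len(batch)
        train_loss, train_acc = _eval(x_train, y_train)
        val_loss, val_acc = _eval(x_val, y_val)
        history["loss"].append(train_loss)
        history["accuracy"].append(train_acc)
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        history["lr"].append(opt.lr)

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_weights = model.get_weights()
            since_improve = 0
        else:
            since_improve += 1
            if config.lr_patience > 0 and since_improve % config.lr_patience == 0:
                opt.lr *= config.lr_factor
            if since_improve > config.early_stop_patience:
                break

    model.set_weights(best_weights)
    return history


def evaluate_model(
    model: nn.Network,
    x_test: np.ndarray,
    y_test: np.ndarray,
    class_names: tuple[str, ...] = CLASS_LABELS,
) -> EvalReport:
    """Test-set evaluation: accuracy (percent), per-class P/R/F1
    (percent), confusion matrix (rows = true), one-vs-rest ROC AUC.

    A class absent from the test set gets NaN ROC AUC; the rest are
    computed normally.
    """
    if len(x_test) == 0:
        raise InvalidArgumentError("test set is empty")
    probs = model.predict_proba(x_test)
    y_true = y_test.argmax(axis=1)
    y_pred = probs.argmax(axis=1)
    k = len(class_names)
    confusion = _sk_confusion(y_true, y_pred, labels=range(k))
    accuracy = 100.0 * np.trace(confusion) / len(y_true)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=range(k), zero_division=0
    )
    roc = {}
    for c, name in enumerate(class_names):
        present = np.any(y_true == c) and np.any(y_true != c)
        roc[name] = (
            float(roc_auc_score((y_true == c).astype(int), probs[:, c]))
            if present
            else float("nan")
        )
    return EvalReport(
        accuracy=float(accuracy),
        precision={n_: 100.0 * p for n_, p in zip(class_names, prec)},
        recall={n_: 100.0 * r for n_, r in zip(class_names, rec)},
        f1={n_: 100.0 * f for n_, f in zip(class_names, f1)},
        confusion=confusion,
        roc_auc=roc,
        n_test=len(y_true),
        class_names=tuple(class_names),
    )


@dataclass
class SubjectSummary:
    mean_accuracy: float
    sd_accuracy: float
    best_subject: int | str
    best_accuracy: float
    n_subjects: int
    accuracies: list[float] = field(default_factory=list)


def aggregate_subjects(reports: dict | list) -> SubjectSummary:
    """Cross-subject mean, sample SD (n-1; 0 for a single subject) and
    best-subject accuracy."""
    if isinstance(reports, dict):
        ids = list(reports.keys())
        accs = [r.accuracy if isinstance(r, EvalReport) else float(r)
                for r in reports.values()]
    else:
        ids = list(range(len(reports)))
        accs = [r.accuracy if isinstance(r, EvalReport) else float(r)
                for r in reports]
    if not accs:
        raise InvalidArgumentError("need at least one report")
    accs_arr = np.asarray(accs, dtype=float)
    sd = 0.0 if accs_arr.size == 1 else float(np.std(accs_arr, ddof=1))
    best = int(np.argmax(accs_arr))
    return SubjectSummary(
        mean_accuracy=float(accs_arr.mean()),
        sd_accuracy=sd,
        best_subject=ids[best],
        best_accuracy=float(accs_arr[best]),
        n_subjects=accs_arr.size,
        accuracies=accs,
    )


def run_subject(
    matrices: np.ndarray,
    labels: list[str],
    variant: str,
    metric: str,
    config: TrainConfig,
) -> tuple[EvalReport, dict[str, list[float]]]:
    """Split one subject's matrices, train a variant and evaluate it."""
    labels = list(labels)
    tr, va, te = split_dataset(labels, config.split_ratios, seed=config.seed)
    x = prepare_inputs(np.asarray(matrices), variant)
    y = encode_labels(labels)
    x_tr, x_va, x_te = scale_features(x[tr], x[va], x[te], metric=metric)
    model = build_model(variant, seed=config.seed)
    history = train_model(model, x_tr, y[tr], x_va, y[va], config)
    report = evaluate_model(model, x_te, y[te])
    return report, history


def save_checkpoint(path: str | Path, model: nn.Network, variant: str) -> None:
    """Persist weights (.npz) plus the architecture description (.json)."""
    path = Path(path)
    weights = {f"w{k}": w for k, w in enumerate(model.get_weights())}
    np.savez(path.with_suffix(".npz"), **weights)
    path.with_suffix(".json").write_text(model_spec(variant).to_json())


def load_checkpoint(path: str | Path, seed: int = 0) -> tuple[nn.Network, str]:
    """Rebuild a network from a checkpoint written by save_checkpoint."""
    path = Path(path)
    arch = json.loads(path.with_suffix(".json").read_text())
    model = build_model(arch["variant"], seed=seed)
    npz = np.load(path.with_suffix(".npz"))
    model.set_weights([npz[f"w{k}"] for k in range(len(npz.files))])
    return model, arch["variant"]
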