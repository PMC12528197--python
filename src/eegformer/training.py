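"""Training loop, metric suite, noise-robustness sweep, ablation grid.

The model is fit by Adam on the combined objective

    L = cross-entropy + mask_lambda * L_mask + mask_sparsity_lambda * mean(M),

with epoch-level stratified train/val/test splits and early stopping on
validation loss.  Evaluation reports accuracy, precision, recall,
specificity, F1 and AUC (binary, or macro one-vs-rest for K > 2); AUC is
the rank-based (Mann-Whitney) estimator via :func:`sklearn.roc_auc_score`.
Robustness is probed by re-evaluating on copies of the held-out data with
Gaussian noise added at a given percentage of each epoch-channel's
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm

from .containers import EpochSet
from .features import frame
from .model import EEGTransformer, ModelConfig
from .synth import add_gaussian_noise_epochs

__all__ = [
    "TrainSpec",
    "MetricsReport",
    "TrainResult",
    "Adam",
    "stratified_split",
    "train",
    "evaluate",
    "noise_robustness",
    "ablation_grid",
    "binary_metrics_from_counts",
]

METRIC_COLUMNS = ("accuracy", "precision", "recall", "specificity", "f1", "auc")


@dataclass
class TrainSpec:
    lr: float = 0.001
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def validate(self) -> None:
        if not np.isclose(sum(self.split), 1.0):
            raise ValueError("split fractions must sum to 1")
        if min(self.split[:2]) <= 0:
            raise ValueError("train and validation fractions must be positive")


@dataclass
class MetricsReport:
    """The six-metric suite plus the confusion matrix it derives from."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    auc: float
    confusion: np.ndarray
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_COLUMNS}

    def row(self) -> list[float]:
        return [getattr(self, k) for k in METRIC_COLUMNS]


@dataclass
class TrainResult:
    model: EEGTransformer
    history: list[dict]
    classes: list
    splits: dict[str, np.ndarray]
    test_set: EpochSet


class Adam:
    """Adam over a named-parameter dict."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def stratified_split(
    labels: np.ndarray, fractions: tuple[float, float, float], seed: int
) -> dict[str, np.ndarray]:
    """Disjoint train/val/test index sets, stratified per class."""
    rng = np.random.default_rng(seed)
    idx = {"train": [], "val": [], "test": []}
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        members = rng.permutation(members)
        n = len(members)
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        idx["train"].append(members[:n_tr])
        idx["val"].append(members[n_tr : n_tr + n_va])
        idx["test"].append(members[n_tr + n_va :])
    return {k: np.sort(np.concatenate(v)) for k, v in idx.items()}


def _frames_for(model_cfg: ModelConfig, data: EpochSet) -> np.ndarray:
    return frame(data, n_frames=model_cfg.seq_len, layout=model_cfg.layout).frames


def train(
    data: EpochSet, config: ModelConfig, spec: TrainSpec | None = None
) -> TrainResult:
    """Fit the transformer on a labeled EpochSet.  Deterministic in seed."""
    spec = spec or TrainSpec()
    spec.validate()
    if data.labels is None:
        raise ValueError("training data must carry per-epoch labels")
    classes = sorted(np.unique(data.labels).tolist())
    if len(classes) < 2:
        raise ValueError("need at least two classes to train a classifier")
    y = np.searchsorted(classes, data.labels)
    counts = np.bincount(y)
    if counts.min() < 10:
        raise ValueError("need at least 10 epochs per class")
    if config.n_classes != len(classes):
        raise ValueError(
            f"config.n_classes={config.n_classes} but data has {len(classes)} classes"
        )

    splits = stratified_split(data.labels, spec.split, spec.seed)
    frames = _frames_for(config, data)
    tr, va = splits["train"], splits["val"]

    model = EEGTransformer(config)
    model.classes_ = classes
    opt = Adam(model.params, lr=spec.lr)
    rng = np.random.default_rng(spec.seed + 1)
    drop_rng = np.random.default_rng(spec.seed + 2)

    history: list[dict] = []
    best = {"val": np.inf, "params": None, "epoch": -1}
    step = 0
    for epoch in range(spec.max_epochs):
        order = rng.permutation(tr)
        for i in range(0, len(order), spec.batch_size):
            batch = order[i : i + spec.batch_size]
            losses, grads = model.loss_and_grads(
                frames[batch], y[batch], train=True, dropout_rng=drop_rng
            )
            if not np.isfinite(losses["total"]):
                raise RuntimeError(
                    f"training diverged at step {step}: loss={losses['total']}"
                )
            opt.step(model.params, grads)
            history.append({"step": step, "epoch": epoch, **losses})
            step += 1
        val_losses = _batched_loss(model, frames[va], y[va], spec.batch_size)
        history.append({"step": step, "epoch": epoch, "val_total": val_losses})
        if val_losses < best["val"] - 1e-12:
            best = {
                "val": val_losses,
                "params": {k: v.copy() for k, v in model.params.items()},
                "epoch": epoch,
            }
        elif epoch - best["epoch"] >= spec.patience:
            break
    if best["params"] is not None:
        model.params = best["params"]
    return TrainResult(model, history, classes, splits, data.subset(splits["test"]))


def _batched_loss(model, frames, y, batch_size) -> float:
    total, n = 0.0, 0
    for i in range(0, len(y), batch_size):
        sl = slice(i, i + batch_size)
        total += model.loss(frames[sl], y[sl])["total"] * len(y[sl])
        n += len(y[sl])
    return total / max(n, 1)


def _per_class_rates(conf: np.ndarray):
    k = conf.shape[0]
    tp = np.diag(conf).astype(float)
    fp = conf.sum(axis=0) - tp
    fn = conf.sum(axis=1) - tp
    tn = conf.sum() - tp - fp - fn
    return tp, fp, fn, tn, k


def binary_metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Metric suite from a binary confusion table (AUC not derivable)."""
    def _div(a, b):
        return a / b if b else np.nan

    precision = _div(tp, tp + fp)
    recall = _div(tp, tp + fn)
    return {
        "accuracy": _div(tp + tn, tp + fp + fn + tn),
        "precision": precision,
        "recall": recall,
        "specificity": _div(tn, tn + fp),
        "f1": _div(2 * precision * recall, precision + recall)
        if np.isfinite(precision) and np.isfinite(recall)
        else np.nan,
    }


def evaluate(
    model: EEGTransformer, data: EpochSet, classes: list | None = None
) -> MetricsReport:
    """Score held-out epochs.  Metrics that are undefined on the given
    data (absent class, degenerate scores) come back as NaN and are named
    in ``report.undefined`` rather than silently zeroed."""
    classes = classes or getattr(model, "classes_", None)
    if classes is None:
        raise ValueError("no class order: pass `classes` or train the model first")
    if data.labels is None:
        raise ValueError("evaluation data must carry labels")
    y = np.searchsorted(classes, data.labels)
    frames = _frames_for(model.config, data)
    probs = model.predict_proba(frames)
    pred = probs.argmax(axis=1)
    k = len(classes)
    conf = _skm.confusion_matrix(y, pred, labels=np.arange(k))
    tp, fp, fn, tn, _ = _per_class_rates(conf)

    undefined = []
    present = np.unique(y)
    if len(present) < k:
        undefined.append("classes absent from evaluation data")

    with np.errstate(invalid="ignore", divide="ignore"):
        prec_c = tp / (tp + fp)
        rec_c = tp / (tp + fn)
        spec_c = tn / (tn + fp)
        f1_c = 2 * prec_c * rec_c / (prec_c + rec_c)

    if k == 2:
        precision, recall, spec, f1 = prec_c[1], rec_c[1], spec_c[1], f1_c[1]
    else:
        precision, recall, spec, f1 = (
            np.nanmean(v) for v in (prec_c, rec_c, spec_c, f1_c)
        )
    accuracy = conf.trace() / conf.sum()

    try:
        if k == 2:
            auc = _skm.roc_auc_score(y, probs[:, 1])
        else:
            auc = _skm.roc_auc_score(y, probs, multi_class="ovr", average="macro")
    except ValueError:
        auc = np.nan
        undefined.append("auc")
    for name, value in zip(("precision", "recall", "specificity", "f1"),
                           (precision, recall, spec, f1)):
        if not np.isfinite(value):
            undefined.append(name)
    return MetricsReport(
        float(accuracy), float(precision), float(recall), float(spec),
        float(f1), float(auc), conf, undefined,
    )


def noise_robustness(
    model: EEGTransformer,
    clean: EpochSet,
    levels: list[float],
    seed: int = 0,
    classes: list | None = None,
) -> dict[float, MetricsReport]:
    """Re-evaluate on noisy copies of the held-out data.

    Noise at X% means additive Gaussian noise with standard deviation
    X/100 of each epoch-channel's clean SD.  Level 0 reproduces the clean
    report exactly.
    """
    if not levels:
        raise ValueError("need at least one noise level")
    child = np.random.SeedSequence(seed).generate_state(len(levels)) % (2**31)
    out = {}
    for level, s in zip(levels, child):
        noisy = add_gaussian_noise_epochs(clean, level, int(s))
        out[level] = evaluate(model, noisy, classes)
    return out


def ablation_grid(
    data: EpochSet,
    heads=(4, 8, 12),
    depths=(3, 6),
    lrs=(0.001,),
    base_config: ModelConfig | None = None,
    train_spec: TrainSpec | None = None,
) -> list[dict]:
    """Train/evaluate every (heads, depth, lr) cell with a shared seed."""
    if not (len(heads) and len(depths) and len(lrs)):
        raise ValueError("ablation grid must be non-empty")
    base = (base_config or ModelConfig()).to_dict()
    spec = train_spec or TrainSpec()
    rows = []
    for h in heads:
        for depth in depths:
            for lr in lrs:
                cfg = ModelConfig(**{**base, "n_heads": h, "n_layers": depth})
                cell_spec = TrainSpec(**{**spec.__dict__, "lr": lr})
                result = train(data, cfg, cell_spec)
                report = evaluate(result.model, result.test_set)
                rows.append(
                    {"heads": h, "depth": depth, "lr": lr, **report.as_dict()}
                )
    return rows


def ablation_to_csv(rows: list[dict], path) -> None:
    cols = ["heads", "depth", "lr", *METRIC_COLUMNS]
    with open(path, "w") as f:
        f.write(",".join(cols) + "\n")
        for r in rows:
            f.write(",".join(str(r[c]) for c in cols) + "\n")
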