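"""Training (Nesterov-momentum SGD with a per-epoch scheduler) and evaluation.

The optimizer follows the interim-gradient formulation: with momentum m,
velocity v and per-epoch learning rate eps,

    theta_interim = theta + m * v
    g             = grad L(theta_interim)   (+ weight_decay * theta_interim)
    v            <- m * v - eps * g
    theta        <- theta + v

The learning rate is recomputed once per epoch from the configured
scheduler; with m = 0 and no decay the update reduces to plain SGD.

Evaluation produces a confusion matrix plus accuracy, macro
precision/recall/F-measure, the Matthews correlation coefficient and
macro one-vs-rest AUC.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .architectures import Network, softmax
from .schedulers import Scheduler

__all__ = [
    "TrainConfig",
    "EpochRecord",
    "nesterov_step",
    "cross_entropy",
    "train",
    "train_repeats",
    "evaluate",
    "confusion_matrix",
    "mcc",
    "macro_precision_recall_f",
    "EvalReport",
    "format_mean_std",
    "make_manifest",
]


@dataclass
class TrainConfig:
    batch_size: int = 20
    momentum: float = 0.9
    weight_decay: float = 1e-4
    epochs: int = 300
    seed: int = 0
    repeats: int = 3
    augment: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must lie in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def to_dict(self) -> dict:
        return {
            "batch_size": self.batch_size,
            "momentum": self.momentum,
            "weight_decay": self.weight_decay,
            "epochs": self.epochs,
            "seed": self.seed,
            "repeats": self.repeats,
            "augment": self.augment,
        }


def nesterov_step(
    theta: Sequence[np.ndarray],
    velocity: Sequence[np.ndarray],
    grad_fn: Callable[[Sequence[np.ndarray]], Tuple[float, Sequence[np.ndarray]]],
    lr: float,
    momentum: float,
    weight_decay: float = 0.0,
) -> float:
    """One optimizer step, updating ``theta`` and ``velocity`` in place.

    ``grad_fn`` receives the interim point and returns (loss, gradients).
    Raises if the loss is non-finite.
    """
    interim = [t + momentum * v for t, v in zip(theta, velocity)]
    loss, grads = grad_fn(interim)
    if not math.isfinite(loss):
        raise FloatingPointError(
            f"non-finite loss {loss!r} at lr={lr}, momentum={momentum}; "
            "training aborted"
        )
    for t, v, ti, g in zip(theta, velocity, interim, grads):
        g_eff = g + weight_decay * ti
        v[...] = momentum * v - lr * g_eff
        t[...] += v
    return loss


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    eps = 1e-12
    loss = -float(np.mean(np.log(probs[np.arange(n), y] + eps)))
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    lr: float
    loss: float
    accuracy: float


def train(
    model: Network,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    scheduler: Scheduler,
    augment_fn: Optional[Callable[[np.ndarray, np.random.Generator], np.ndarray]] = None,
    epochs: Optional[int] = None,
    callback: Optional[Callable[[EpochRecord], bool]] = None,
) -> List[EpochRecord]:
    """Train for ``epochs`` (default ``config.epochs``) epochs.

    Returns the per-epoch log of (epoch, learning rate, mean loss, train
    accuracy). ``callback``, if given, sees each record and may return
    True to stop early.
    """
    if X.shape[0] == 0:
        raise ValueError("training set is empty")
    n_epochs = config.epochs if epochs is None else epochs
    rng = np.random.default_rng(config.seed)
    params = model.params()
    theta = [p.value for p in params]
    velocity = [np.zeros_like(t) for t in theta]
    n = X.shape[0]
    log: List[EpochRecord] = []
    for e in range(1, n_epochs + 1):
        lr = float(scheduler(e))
        order = rng.permutation(n)
        losses: List[float] = []
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = X[idx]
            yb = y[idx]
            if config.augment and augment_fn is not None:
                xb = np.stack([augment_fn(img, rng) for img in xb])

            def grad_fn(interim: Sequence[np.ndarray]):
                saved = [t.copy() for t in theta]
                for t, ti in zip(theta, interim):
                    t[...] = ti
                model.zero_grad()
                logits = model.forward(xb, training=True)
                loss, dlogits = cross_entropy(logits, yb)
                model.backward(dlogits)
                grads = [p.grad.copy() for p in params]
                for t, s in zip(theta, saved):
                    t[...] = s
                grad_fn.correct = int((logits.argmax(axis=1) == yb).sum())
                return loss, grads

            loss = nesterov_step(theta, velocity, grad_fn, lr,
                                 config.momentum, config.weight_decay)
            losses.append(loss)
            correct += grad_fn.correct
        record = EpochRecord(epoch=e, lr=lr, loss=float(np.mean(losses)),
                             accuracy=correct / n)
        log.append(record)
        if callback is not None and callback(record):
            break
    return log


def train_repeats(
    model_factory: Callable[[int], Network],
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    scheduler: Scheduler,
    **kwargs,
) -> List[Tuple[Network, List[EpochRecord]]]:
    """Run ``config.repeats`` independent trainings with distinct seeds."""
    runs = []
    for i in range(config.repeats):
        seed = config.seed + i
        model = model_factory(seed)
        cfg = TrainConfig(**{**config.to_dict(), "seed": seed, "repeats": 1})
        log = train(model, X, y, cfg, scheduler, **kwargs)
        runs.append((model, log))
    return runs


def format_mean_std(values: Sequence[float], decimals: int = 2) -> str:
    """Repeat-protocol summary string, e.g. ``98.87 ± 0.10``."""
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    std = arr.std(ddof=1) if arr.size > 1 else 0.0
    return f"{mean:.{decimals}f} ± {std:.{decimals}f}"


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, num_classes: int) -> np.ndarray:
    """Integer K x K matrix, rows = true class, columns = predicted class."""
    conf = np.zeros((num_classes, num_classes), dtype=np.int64)
    for t, p in zip(np.asarray(y_true).ravel(), np.asarray(y_pred).ravel()):
        conf[int(t), int(p)] += 1
    return conf


def _validate_confusion(conf: np.ndarray) -> np.ndarray:
    conf = np.asarray(conf)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError(f"confusion matrix must be square, got shape {conf.shape}")
    if np.any(conf < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    return conf.astype(np.int64)


def mcc(conf: np.ndarray) -> float:
    """Matthews correlation coefficient from a confusion matrix.

    Binary matrices use the classical TP/TN/FP/FN formula; larger
    matrices use the multi-category generalization over the full matrix.
    Returns 0 when any marginal vanishes (degenerate denominator).
    """
    conf = _validate_confusion(conf)
    k = conf.shape[0]
    if k == 2:
        tn, fp = conf[0, 0], conf[0, 1]
        fn, tp = conf[1, 0], conf[1, 1]
        denom_sq = float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
        if denom_sq == 0.0:
            return 0.0
        return float((tp * tn - fp * fn) / math.sqrt(denom_sq))
    c = conf.astype(float)
    s = c.sum()
    trace = np.trace(c)
    t_k = c.sum(axis=1)  # true-class totals
    p_k = c.sum(axis=0)  # predicted-class totals
    num = trace * s - float(t_k @ p_k)
    denom = math.sqrt(max(s * s - float(p_k @ p_k), 0.0)) * math.sqrt(
        max(s * s - float(t_k @ t_k), 0.0)
    )
    if denom == 0.0:
        return 0.0
    return float(num / denom)


def macro_precision_recall_f(conf: np.ndarray) -> Tuple[float, float, float, List[Dict[str, float]]]:
    """Unweighted per-class averages; empty-class precision/recall are 0."""
    conf = _validate_confusion(conf)
    k = conf.shape[0]
    per_class: List[Dict[str, float]] = []
    for i in range(k):
        tp = float(conf[i, i])
        predicted = float(conf[:, i].sum())
        actual = float(conf[i, :].sum())
        prec = tp / predicted if predicted > 0 else 0.0
        rec = tp / actual if actual > 0 else 0.0
        f = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
        per_class.append({"precision": prec, "recall": rec, "f_measure": f})
    macro_p = float(np.mean([c["precision"] for c in per_class]))
    macro_r = float(np.mean([c["recall"] for c in per_class]))
    macro_f = float(np.mean([c["f_measure"] for c in per_class]))
    return macro_p, macro_r, macro_f, per_class


@dataclass
class EvalReport:
    confusion: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f_measure: float
    mcc: float
    auc: Optional[float]
    per_class: List[Dict[str, float]]
    class_names: List[str]

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f_measure": self.macro_f_measure,
            "mcc": self.mcc,
            "auc": self.auc,
            "per_class": self.per_class,
            "class_names": self.class_names,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate(
    model: Network,
    X: np.ndarray,
    y: np.ndarray,
    class_names: Optional[Sequence[str]] = None,
) -> EvalReport:
    """Full test-set report; AUC is macro one-vs-rest on probabilities and
    reported as None when the test set contains a single class."""
    if X.shape[0] == 0:
        raise ValueError("test set is empty")
    probs = model.predict_proba(X)
    return report_from_probs(probs, y, class_names=class_names)


def report_from_probs(
    probs: np.ndarray,
    y: np.ndarray,
    class_names: Optional[Sequence[str]] = None,
) -> EvalReport:
    k = probs.shape[1]
    names = list(class_names) if class_names is not None else [str(i) for i in range(k)]
    preds = probs.argmax(axis=1)
    conf = confusion_matrix(y, preds, k)
    acc = float(np.trace(conf) / conf.sum())
    macro_p, macro_r, macro_f, per_class = macro_precision_recall_f(conf)
    auc: Optional[float]
    if len(np.unique(y)) < 2:
        auc = None
    else:
        from sklearn.metrics import roc_auc_score

        if k == 2:
            auc = float(roc_auc_score(y, probs[:, 1]))
        else:
            auc = float(roc_auc_score(y, probs, multi_class="ovr",
                                      average="macro", labels=list(range(k))))
    return EvalReport(
        confusion=conf,
        accuracy=acc,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f_measure=macro_f,
        mcc=mcc(conf),
        auc=auc,
        per_class=per_class,
        class_names=names,
    )


def make_manifest(config: TrainConfig, seeds: Sequence[int], extra: Optional[dict] = None) -> dict:
    """Reproducibility manifest: seeds, config hash, package version."""
    from . import __version__

    cfg = config.to_dict()
    digest = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    manifest = {
        "config": cfg,
        "config_hash": digest,
        "seeds": list(seeds),
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    return manifest
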