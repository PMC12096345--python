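"""Evaluation: accuracy, macro precision/recall/F1, confusion matrix.

Metrics are reported in percent. Macro averages run over the classes
present in the test set (the evaluation sets here are class-balanced by
construction); a class with an undefined precision or recall
contributes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ModelReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray
    classes: tuple
    misclassifications: tuple[tuple[object, object, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        c = np.asarray(self.confusion, dtype=int)
        object.__setattr__(self, "confusion", c)
        if np.any(c < 0):
            raise ValueError("confusion matrix entries must be >= 0")

    @property
    def n_test(self) -> int:
        return int(self.confusion.sum())

    def as_row(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.macro_precision,
            "recall": self.macro_recall,
            "f1": self.macro_f1,
        }


def report_from_predictions(y_true, y_pred, classes=None) -> ModelReport:
    """Build a report directly from label vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty test set")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true/y_pred length mismatch")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = list(classes)
    index = {c: k for k, c in enumerate(classes)}
    unknown = sorted({v for v in np.concatenate([y_true, y_pred]) if v not in index})
    if unknown:
        raise ValueError(f"labels outside the class list: {unknown}")
    k = len(classes)
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[index[t], index[p]] += 1
    accuracy = 100.0 * np.trace(conf) / conf.sum()
    present = conf.sum(axis=1) > 0
    precisions, recalls, f1s = [], [], []
    for i in np.flatnonzero(present):
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        precisions.append(p)
        recalls.append(r)
        f1s.append(2 * p * r / (p + r) if p + r > 0 else 0.0)
    errors: dict[tuple, int] = {}
    for t, p in zip(y_true, y_pred):
        if t != p:
            errors[(t, p)] = errors.get((t, p), 0) + 1
    ranked = tuple(sorted(((t, p, n) for (t, p), n in errors.items()),
                          key=lambda item: (-item[2], str(item[0]), str(item[1]))))
    return ModelReport(
        accuracy=float(accuracy),
        macro_precision=100.0 * float(np.mean(precisions)),
        macro_recall=100.0 * float(np.mean(recalls)),
        macro_f1=100.0 * float(np.mean(f1s)),
        confusion=conf,
        classes=tuple(classes),
        misclassifications=ranked,
    )


def evaluate(model, x, y_true, classes=None) -> ModelReport:
    """Score a trained model (anything with ``predict_proba``) on a test set.

    ``y_true`` holds integer labels; ``classes`` optionally names them.
    Labels outside the model's output width raise.
    """
    y_true = np.asarray(y_true)
    if len(y_true) == 0:
        raise ValueError("empty test set")
    probs = model.predict_proba(x)
    if y_true.max() >= probs.shape[1] or y_true.min() < 0:
        raise ValueError("test labels outside the model's class range")
    y_pred = probs.argmax(axis=1)
    if classes is not None:
        names = list(classes)
        y_true = np.asarray([names[i] for i in y_true], dtype=object)
        y_pred = np.asarray([names[i] for i in y_pred], dtype=object)
        return report_from_predictions(y_true, y_pred, classes=names)
    return report_from_predictions(y_true, y_pred, classes=list(range(probs.shape[1])))
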