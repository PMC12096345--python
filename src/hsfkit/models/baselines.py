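"""One-vs-rest classical baselines with the stated hyperparameter grid.

Logistic regression, random forest and SVM, each wrapped as a
one-vs-rest classifier, searched over regularization strengths
{0.0, 0.2, 0.4, 0.6, 0.8, 1.0}, SVM kernels {linear, poly, rbf,
sigmoid} and PCA widths {25, 50, 75, 100} (plus no-PCA) by k-fold
selection on the training split.

Strength-to-parameter mapping: the libraries parameterize penalties
inversely (C), so strength s > 0 maps to C = 1/s and s = 0.0 maps to a
penalty-free fit (``penalty=None`` for logistic regression; C = 1e6 for
SVM, which cannot disable its penalty exactly). Random forests carry no
comparable strength and are searched over PCA only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

ALGORITHMS = ("lr", "rf", "svm")
_UNPENALIZED_C = 1e6

_KERNEL_ALIASES = {"linear": "linear", "polynomial": "poly", "poly": "poly",
                   "radial-basis-function": "rbf", "rbf": "rbf", "sigmoid": "sigmoid"}


@dataclass(frozen=True)
class BaselineSpec:
    algorithm: str
    regularization_strengths: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    kernels: tuple[str, ...] = ("linear", "poly", "rbf", "sigmoid")
    pca_components: tuple[int, ...] = (25, 50, 75, 100)
    include_no_pca: bool = True
    cv_folds: int = 3
    n_estimators: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        bad = [k for k in self.kernels if k not in _KERNEL_ALIASES]
        if bad:
            raise ValueError(f"unknown kernels: {bad}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def candidate_grid(spec: BaselineSpec) -> list[dict]:
    """Enumerate the full hyperparameter grid for one algorithm.

    Kernels apply to SVM only; regularization strengths apply to LR and
    SVM; every algorithm is crossed with the PCA options (plus no-PCA
    when enabled).
    """
    pca_opts: list[int | None] = list(spec.pca_components)
    if spec.include_no_pca:
        pca_opts = [None, *pca_opts]
    grid: list[dict] = []
    if spec.algorithm == "svm":
        for s in spec.regularization_strengths:
            for kern in spec.kernels:
                for pca in pca_opts:
                    grid.append({"strength": s, "kernel": _KERNEL_ALIASES[kern], "pca": pca})
    elif spec.algorithm == "lr":
        for s in spec.regularization_strengths:
            for pca in pca_opts:
                grid.append({"strength": s, "pca": pca})
    else:  # rf
        for pca in pca_opts:
            grid.append({"pca": pca})
    return grid


def _make_estimator(spec: BaselineSpec, cand: dict) -> Pipeline:
    if spec.algorithm == "lr":
        s = cand["strength"]
        if s == 0.0:
            base = LogisticRegression(penalty=None, max_iter=2000)
        else:
            base = LogisticRegression(C=1.0 / s, max_iter=2000)
    elif spec.algorithm == "svm":
        s = cand["strength"]
        c = _UNPENALIZED_C if s == 0.0 else 1.0 / s
        base = SVC(kernel=cand["kernel"], C=c)
    else:
        base = RandomForestClassifier(n_estimators=spec.n_estimators, random_state=spec.seed)
    steps = []
    if cand.get("pca") is not None:
        steps.append(("pca", PCA(n_components=cand["pca"], random_state=spec.seed)))
    steps.append(("ovr", OneVsRestClassifier(base)))
    return Pipeline(steps)


class FittedBaseline:
    """A refit best candidate plus a normalized probability interface."""

    def __init__(self, spec: BaselineSpec, pipeline: Pipeline, best_params: dict,
                 cv_score: float, n_classes: int):
        self.spec = spec
        self.pipeline = pipeline
        self.best_params = best_params
        self.cv_score = cv_score
        self.n_classes = n_classes

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = _flatten(x)
        ovr = self.pipeline.named_steps["ovr"]
        if hasattr(ovr, "decision_function"):
            scores = self.pipeline.decision_function(x)
            if scores.ndim == 1:  # binary OvR collapses to one column
                scores = np.column_stack([-scores, scores])
            # softmax over per-class decision scores -> proper distribution
            scores = scores - scores.max(axis=1, keepdims=True)
            e = np.exp(scores)
            return e / e.sum(axis=1, keepdims=True)
        probs = self.pipeline.predict_proba(x)
        return probs / probs.sum(axis=1, keepdims=True)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


def _flatten(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim > 2:
        x = x.reshape(len(x), -1)
    elif x.ndim == 1:
        x = x[None, :]
    return x


def _cv_accuracy(spec: BaselineSpec, cand: dict, x: np.ndarray, y: np.ndarray) -> float:
    """Mean k-fold accuracy; folds whose training half misses a class are skipped."""
    n = len(x)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    folds = np.array_split(order, spec.cv_folds)
    all_classes = set(np.unique(y))
    scores = []
    for k, test_idx in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != k])
        if set(np.unique(y[train_idx])) != all_classes or len(test_idx) == 0:
            warnings.warn(f"fold {k}: class missing from training half, fold skipped",
                          stacklevel=2)
            continue
        est = _make_estimator(spec, cand)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(x[train_idx], y[train_idx])
            pred = est.predict(x[test_idx])
        scores.append(float(np.mean(pred == y[test_idx])))
    if not scores:
        raise ValueError("no usable cross-validation folds")
    return float(np.mean(scores))


def fit_baseline(spec: BaselineSpec, x: np.ndarray, y: np.ndarray,
                 seed: int | None = None) -> FittedBaseline:
    """Exhaustive grid search, k-fold selection, refit of the winner.

    Candidates whose PCA width exceeds the data dimensions are skipped
    with a warning. Ties break toward the earlier grid entry.
    """
    if seed is not None and seed != spec.seed:
        from dataclasses import replace

        spec = replace(spec, seed=seed)
    x = _flatten(x)
    y = np.asarray(y)
    if len(x) == 0:
        raise ValueError("training set is empty")
    best: tuple[float, int, dict] | None = None
    for rank, cand in enumerate(candidate_grid(spec)):
        pca = cand.get("pca")
        if pca is not None and pca > min(x.shape):
            warnings.warn(f"skipping candidate {cand}: PCA width exceeds data size",
                          stacklevel=2)
            continue
        score = _cv_accuracy(spec, cand, x, y)
        if best is None or score > best[0]:
            best = (score, rank, cand)
    if best is None:
        raise ValueError("no feasible candidates in the grid")
    score, _rank, cand = best
    pipeline = _make_estimator(spec, cand)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pipeline.fit(x, y)
    return FittedBaseline(spec, pipeline, cand, score, n_classes=len(np.unique(y)))
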