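"""Soft-margin SVM with stratified 10-fold cross-validation.

The classifier solves the usual soft-margin problem
min ||w||^2 / 2 + C * sum(xi_i), optionally kernelized (RBF by default).
Evaluation follows the study protocol: stratified k-fold over segments,
per-fold standardization fitted on the training fold only, an inner
grid search over (C, kernel width) on the training fold, then refit and
score on the held-out fold.  Reported metrics are accuracy, sensitivity,
precision and F1 with ADHD as the positive class, as mean +/- sample SD
over folds plus the pooled confusion counts.

Segment-wise folding (the default) can place segments of one subject in
both train and test folds; pass groups= to switch to leakage-safe
subject-wise folding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedGroupKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["SVMConfig", "CVReport", "compute_metrics", "run_cv"]

POSITIVE_CLASS = "ADHD"
METRICS = ("accuracy", "sensitivity", "precision", "f1")


@dataclass
class SVMConfig:
    """Kernel SVM settings and the inner hyperparameter search grid.

    kernel_width is the RBF gamma; the default grid scales {0.1, 1, 10}
    by 1/d where d is the feature count.  The inner search uses training
    folds only.
    """

    kernel: str = "rbf"
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    width_grid: tuple[float, ...] | None = None  # None -> {0.1, 1, 10}/d
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError(f"kernel must be 'rbf' or 'linear', got {self.kernel!r}")
        if not self.c_grid:
            raise ValueError("C grid must be nonempty")

    def param_grid(self, n_features: int) -> dict:
        grid = {"svc__C": list(self.c_grid)}
        if self.kernel == "rbf":
            widths = self.width_grid or tuple(
                w / n_features for w in (0.1, 1.0, 10.0)
            )
            grid["svc__gamma"] = list(widths)
        return grid


@dataclass
class CVReport:
    """Per-fold and aggregate cross-validation metrics."""

    per_fold: dict[str, list[float]]
    mean_sd: dict[str, tuple[float, float]]
    confusion_total: dict[str, int]
    positive_class: str = POSITIVE_CLASS
    folds: int = 10

    def to_dict(self) -> dict:
        return {
            "positive_class": self.positive_class,
            "folds": self.folds,
            "per_fold": self.per_fold,
            "mean_sd": {k: list(v) for k, v in self.mean_sd.items()},
            "confusion_total": self.confusion_total,
        }

    def to_markdown(self) -> str:
        """Mean +/- SD table (percent, 2 decimals; SD to 4 decimals)."""
        head = "| Accuracy | Sensitivity | Precision | F1 score |"
        sep = "|---|---|---|---|"
        cells = [
            f"{100 * self.mean_sd[m][0]:.2f} ± {self.mean_sd[m][1]:.4f}"
            for m in METRICS
        ]
        return "\n".join([head, sep, "| " + " | ".join(cells) + " |"])


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Accuracy, sensitivity, precision and F1 from confusion counts.

    Sensitivity is 0 when there are no actual positives, precision 0 when
    nothing was predicted positive, and F1 0 when both are 0.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("confusion counts are all zero")
    acc = (tp + tn) / total
    sens = tp / (tp + fn) if tp + fn > 0 else 0.0
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
    return {"accuracy": acc, "sensitivity": sens, "precision": prec, "f1": f1}


def run_cv(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SVMConfig | None = None,
    folds: int = 10,
    seed: int = 0,
    groups: np.ndarray | None = None,
    feature_selector: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> CVReport:
    """Stratified k-fold CV with per-fold standardization and inner search.

    y holds class tags ("ADHD"/"normal" or any two labels; POSITIVE_CLASS
    is the positive if present, otherwise the lexicographically last label).
    groups, when given, keeps all segments of one subject in a single fold.

    feature_selector, when given, is called with the training fold only and
    must return the column indices to keep; the same indices are applied to
    the held-out fold.  Fitting selection inside each fold keeps the test
    data out of every fitted quantity — selecting once on the full matrix
    before CV would leak labels and inflate accuracy on label-free data.
    """
    cfg = cfg or SVMConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"run_cv expects exactly 2 classes, got {list(classes)}")
    if counts.min() < folds and groups is None:
        raise ValueError(
            f"smallest class has {counts.min()} members; use at most "
            f"{counts.min()} folds"
        )
    pos = POSITIVE_CLASS if POSITIVE_CLASS in classes else classes[-1]
    y_bin = (y == pos).astype(int)

    if groups is None:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y_bin)
    else:
        splitter = StratifiedGroupKFold(
            n_splits=folds, shuffle=True, random_state=seed
        )
        split_iter = splitter.split(X, y_bin, groups=groups)

    per_fold: dict[str, list[float]] = {m: [] for m in METRICS}
    conf = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for train_idx, test_idx in split_iter:
        X_train, X_test = X[train_idx], X[test_idx]
        if feature_selector is not None:
            cols = np.asarray(feature_selector(X_train, y[train_idx]))
            X_train, X_test = X_train[:, cols], X_test[:, cols]
        pipe = Pipeline(
            [("scale", StandardScaler()), ("svc", SVC(kernel=cfg.kernel))]
        )
        search = GridSearchCV(
            pipe,
            cfg.param_grid(X_train.shape[1]),
            scoring="accuracy",
            cv=StratifiedKFold(n_splits=cfg.inner_folds),
            n_jobs=1,
        )
        search.fit(X_train, y_bin[train_idx])
        pred = search.predict(X_test)
        truth = y_bin[test_idx]
        tp = int(np.sum((pred == 1) & (truth == 1)))
        fp = int(np.sum((pred == 1) & (truth == 0)))
        tn = int(np.sum((pred == 0) & (truth == 0)))
        fn = int(np.sum((pred == 0) & (truth == 1)))
        for key, val in zip(("tp", "fp", "tn", "fn"), (tp, fp, tn, fn)):
            conf[key] += val
        fold_metrics = compute_metrics(tp, fp, tn, fn)
        for m in METRICS:
            per_fold[m].append(fold_metrics[m])

    mean_sd = {
        m: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
        for m, v in per_fold.items()
    }
    return CVReport(
        per_fold=per_fold,
        mean_sd=mean_sd,
        confusion_total=conf,
        positive_class=str(pos),
        folds=folds,
    )
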