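"""Nested cross-validation engine for the z-score → PCA → classifier pipeline.

Outer folds estimate generalisation accuracy; the inner loop, run only on
outer-training rows, selects the number of principal components from a
grid (default 2–15). Standardisation and PCA are refit on every training
split — held-out rows never influence any fit (the leakage contract).
A fixed-PC mode skips the inner search, reproducing the fixed-5-PC
analyses whose pooled out-of-fold predictions feed the confusion matrix.

Headline accuracy is the mean of outer-fold accuracies; the pooled
out-of-fold accuracy (trace/total of the pooled confusion matrix) is also
reported, since with the study's data either aggregation could have
produced the published figures.
"""

from __future__ import annotations

import copy
import statistics
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .feature_table import FeatureTable, METADATA_COLUMNS, SchemaError
from .metrics import ClassificationReport, confusion_matrix, per_class_metrics
from .multivariate import KNearestNeighbors, LinearDiscriminant, PrincipalComponents
from .feature_table import Standardizer


class FoldError(ValueError):
    """A fold layout makes the procedure undefined (e.g. a class missing)."""


class SelectionError(ValueError):
    """No candidate PC count is feasible on the inner-training splits."""


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation design.

    ``fixed_pcs`` set ⇒ the inner search is skipped and that PC count used
    on every outer fold. ``classifier`` is "lda", "knn", or any object with
    ``fit(X, y)`` and ``predict(X)`` (a fresh deep copy is used per fold).
    """

    outer_k: int = 5
    inner_k: int = 5
    pc_grid: tuple = tuple(range(2, 16))
    fixed_pcs: Optional[int] = None
    classifier: Union[str, object] = "lda"
    stratified: bool = True
    include_age: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.outer_k < 2 or self.inner_k < 2:
            raise ValueError("outer_k and inner_k must both be >= 2")
        if not self.pc_grid or min(self.pc_grid) < 1:
            raise ValueError("pc_grid must contain positive PC counts")
        if self.fixed_pcs is not None and self.fixed_pcs < 1:
            raise ValueError("fixed_pcs must be positive")


@dataclass(frozen=True)
class FoldPlan:
    """Per-observation outer-fold index in [0, n_folds)."""

    assignments: np.ndarray
    n_folds: int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)


@dataclass(frozen=True)
class NestedCVResult:
    outer_accuracies: tuple
    mean_accuracy: float
    chosen_pcs: tuple
    median_pcs: float
    pooled_true: np.ndarray
    pooled_pred: np.ndarray
    fold_plan: FoldPlan
    label_column: str = ""

    @property
    def pooled_accuracy(self) -> float:
        return float(np.mean(self.pooled_true == self.pooled_pred))

    def to_dict(self) -> dict:
        return {
            "label_column": self.label_column,
            "outer_accuracies": list(self.outer_accuracies),
            "mean_accuracy": self.mean_accuracy,
            "pooled_accuracy": self.pooled_accuracy,
            "chosen_pcs": list(self.chosen_pcs),
            "median_pcs": self.median_pcs,
            "pooled_true": [str(v) for v in self.pooled_true],
            "pooled_pred": [str(v) for v in self.pooled_pred],
            "fold_assignments": self.fold_plan.assignments.tolist(),
        }


def _make_folds(y: np.ndarray, k: int, stratified: bool, rng: np.random.Generator) -> FoldPlan:
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} observations")
    assignments = np.empty(n, dtype=int)
    if stratified:
        fill = np.zeros(k, dtype=int)
        for cls in sorted(set(y)):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            for i in idx:
                f = int(np.argmin(fill))  # least-filled fold, lowest index on ties
                assignments[i] = f
                fill[f] += 1
    else:
        perm = rng.permutation(n)
        sizes = np.full(k, n // k, dtype=int)
        sizes[: n % k] += 1
        start = 0
        for f, size in enumerate(sizes):
            assignments[perm[start : start + size]] = f
            start += size
    return FoldPlan(assignments, k)


def make_folds(labels, k: int, stratified: bool = True, seed: int = 0) -> FoldPlan:
    """Seeded, reproducible k-fold partition, optionally class-stratified.

    Stratification keeps per-class fold sizes within one of each other,
    which with small classes is what keeps every class represented in
    every training split.
    """
    y = np.asarray(labels, dtype=object)
    if stratified and len(set(y)) < 1:
        raise ValueError("stratification needs at least one class")
    return _make_folds(y, k, stratified, np.random.default_rng(seed))


def _make_classifier(choice: Union[str, object]):
    if isinstance(choice, str):
        if choice == "lda":
            return LinearDiscriminant()
        if choice == "knn":
            return KNearestNeighbors(k=5)
        raise ValueError(f"unknown classifier {choice!r} (use 'lda', 'knn' or an object)")
    if not (hasattr(choice, "fit") and hasattr(choice, "predict")):
        raise ValueError("plug-in classifier must provide fit(X, y) and predict(X)")
    return copy.deepcopy(choice)


def _select_pcs(X: np.ndarray, y: np.ndarray, config: CVConfig, rng: np.random.Generator) -> int:
    """Inner-loop grid search over PC counts; ties go to the smallest count."""
    grid = sorted(set(int(c) for c in config.pc_grid))
    plan = _make_folds(y, config.inner_k, config.stratified, rng)
    p = X.shape[1]
    # feasibility bound: the smallest inner-training split caps the PC count
    min_train = min(
        len(y) - len(plan.fold_indices(f)) for f in range(config.inner_k)
    )
    cap = min(min_train - 1, p)
    feasible = [c for c in grid if c <= cap]
    if not feasible:
        raise SelectionError(
            f"no PC count in grid {grid} is feasible (cap {cap})"
        )
    if len(feasible) == 1:
        return feasible[0]
    kmax = max(feasible)
    fold_accs = {c: [] for c in feasible}
    for f in range(config.inner_k):
        test = plan.assignments == f
        train = ~test
        if len(set(y[train])) < 2:
            raise FoldError("inner-training split retains fewer than 2 classes")
        std = Standardizer().fit(X[train])
        Ztr, Zte = std.transform(X[train]), std.transform(X[test])
        pca = PrincipalComponents(kmax).fit(Ztr)
        Str, Ste = pca.transform(Ztr), pca.transform(Zte)
        # the top-c components of a rank-kmax fit equal a rank-c fit: slice
        for c in feasible:
            clf = _make_classifier(config.classifier)
            clf.fit(Str[:, :c], y[train])
            pred = clf.predict(Ste[:, :c])
            fold_accs[c].append(float(np.mean(pred == y[test])))
    best, best_acc = None, -1.0
    for c in feasible:  # ascending: strict improvement required -> smallest wins ties
        acc = float(np.mean(fold_accs[c]))
        if acc > best_acc:
            best, best_acc = c, acc
    return best


def _run_cv(X: np.ndarray, y: np.ndarray, config: CVConfig, label_column: str = "") -> NestedCVResult:
    config.validate()
    n = len(y)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + config.outer_k)
    plan = _make_folds(y, config.outer_k, config.stratified, np.random.default_rng(children[0]))
    classes = sorted(set(y))
    pooled_pred = np.empty(n, dtype=object)
    accs, chosen = [], []
    for f in range(config.outer_k):
        test = plan.assignments == f
        train = ~test
        missing = [c for c in classes if c not in set(y[train])]
        if missing:
            raise FoldError(
                f"outer fold {f}: class {missing[0]!r} absent from the training split"
            )
        if config.fixed_pcs is not None:
            n_pcs = int(config.fixed_pcs)
        elif len(set(config.pc_grid)) == 1:
            n_pcs = int(next(iter(set(config.pc_grid))))
        else:
            n_pcs = _select_pcs(
                X[train], y[train], config, np.random.default_rng(children[1 + f])
            )
        std = Standardizer().fit(X[train])
        Ztr, Zte = std.transform(X[train]), std.transform(X[test])
        pca = PrincipalComponents(n_pcs).fit(Ztr)
        clf = _make_classifier(config.classifier)
        clf.fit(pca.transform(Ztr), y[train])
        pred = clf.predict(pca.transform(Zte))
        pooled_pred[test] = pred
        accs.append(float(np.mean(pred == y[test])))
        chosen.append(n_pcs)
    return NestedCVResult(
        outer_accuracies=tuple(accs),
        mean_accuracy=float(np.mean(accs)),
        chosen_pcs=tuple(chosen),
        median_pcs=float(statistics.median(chosen)),
        pooled_true=y.copy(),
        pooled_pred=pooled_pred,
        fold_plan=plan,
        label_column=label_column,
    )


def inner_select_pcs(train_matrix, train_labels, config: CVConfig = CVConfig()) -> int:
    """Select the PC count by inner k-fold CV on a training set."""
    X = np.asarray(train_matrix, dtype=float)
    y = np.asarray(train_labels, dtype=object)
    return _select_pcs(X, y, config, np.random.default_rng(config.seed)) if len(
        set(int(c) for c in config.pc_grid)
    ) > 1 else sorted(set(int(c) for c in config.pc_grid))[0]


def nested_cv_run(table: FeatureTable, label_column: str, config: CVConfig = CVConfig()) -> NestedCVResult:
    """Full nested CV on a feature table, classifying by donor or treatment."""
    if label_column not in METADATA_COLUMNS:
        raise SchemaError(f"label column must be one of {METADATA_COLUMNS}")
    X = table.feature_matrix(include_age=config.include_age)
    y = table.labels(label_column)
    return _run_cv(X, y, config, label_column)


def fixed_pc_run(
    table: FeatureTable,
    label_column: str,
    n_pcs: int = 5,
    config: CVConfig = CVConfig(),
) -> tuple[NestedCVResult, ClassificationReport]:
    """Fixed-PC analysis: skip the inner search, report pooled-class metrics.

    Equivalent to :func:`nested_cv_run` with a singleton PC grid; the pooled
    out-of-fold predictions feed the confusion matrix and per-class report.
    """
    cfg = replace(config, fixed_pcs=int(n_pcs))
    result = nested_cv_run(table, label_column, cfg)
    classes = sorted(set(result.pooled_true))
    cm = confusion_matrix(result.pooled_true, result.pooled_pred, classes)
    return result, per_class_metrics(cm)
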