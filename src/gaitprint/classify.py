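"""Linear-SVM classification of GRF stance curves under nested, task-aware CV.

Three tasks are supported on the same 303-value feature vectors:

* ``subject_x_footwear`` — every (subject, footwear) pair is a class; the
  outer 4-fold split distributes each pair's trials equally across folds.
* ``subject`` — classes are subjects; folds are footwear-disjoint
  (leave-one-condition-out: each condition's recordings sit wholly in one
  fold, so the model must recognise a subject in an unseen condition).
* ``footwear`` — classes are conditions; folds are subject-disjoint (the
  model must recognise a condition on unseen subjects).

The classifier is an L2-regularised, L2-loss (squared-hinge) linear SVM in
a one-vs-rest scheme. The regularisation constant C is chosen per outer
fold by a grid search over C = 2^-5, 2^-4.75, ..., 2^15 evaluated with an
inner two-fold split that respects the task's disjointness rule; min-max
feature scaling is fitted on training data only at every level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "TaskSpec",
    "TASKS",
    "LinearStanceSVM",
    "CVReport",
    "c_grid",
    "make_folds",
    "inner_splits",
    "grid_search_C",
    "train_svm",
    "zero_rule_baseline",
    "run_task",
]


def c_grid(low: float = -5.0, high: float = 15.0, step: float = 0.25) -> np.ndarray:
    """Candidate C values 2^low, 2^(low+step), ..., 2^high (default: 81 values)."""
    if step <= 0 or high < low:
        raise ValueError("empty C grid")
    return 2.0 ** np.arange(low, high + step / 2.0, step)


@dataclass(frozen=True)
class TaskSpec:
    """A classification task: how labels are derived and how folds are built."""

    name: str
    label_fn: Callable[[pd.DataFrame], pd.Series]
    fold_rule: str  # per-class-balanced | footwear-disjoint | subject-disjoint


def _sxf_labels(meta: pd.DataFrame) -> pd.Series:
    return meta["subject_id"].astype(str) + "|" + meta["footwear_id"].astype(str)


TASKS: dict[str, TaskSpec] = {
    "subject_x_footwear": TaskSpec("subject_x_footwear", _sxf_labels, "per-class-balanced"),
    "subject": TaskSpec("subject", lambda m: m["subject_id"].astype(str), "footwear-disjoint"),
    "footwear": TaskSpec("footwear", lambda m: m["footwear_id"].astype(str), "subject-disjoint"),
}


class LinearStanceSVM(BaseEstimator, ClassifierMixin):
    """Min-max scaling + one-vs-rest linear SVM (L2-regularised, L2-loss).

    The scaler is fitted inside ``fit``, so any training/test split
    automatically confines min/max estimation to the training data.
    Prediction is ``argmax_k (W_k . x_scaled + b_k)``.

    Fitted attributes: ``scaler_``, ``svc_``, ``classes_``, ``coef_``
    (n_classes x n_features, also for binary problems), ``intercept_``.
    """

    def __init__(self, C: float = 1.0, tol: float = 1e-4, max_iter: int = 5000,
                 random_state: int = 0):
        self.C = C
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X: np.ndarray, y) -> "LinearStanceSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if np.unique(y).size < 2:
            raise ValueError("training data must contain at least 2 classes")
        self.scaler_ = MinMaxScaler(clip=False).fit(X)
        self.svc_ = LinearSVC(
            C=self.C,
            penalty="l2",
            loss="squared_hinge",
            dual=False,
            tol=self.tol,
            max_iter=self.max_iter,
            random_state=self.random_state,
        ).fit(self.scaler_.transform(X), y)
        self.classes_ = self.svc_.classes_
        if self.svc_.coef_.shape[0] == 1:  # binary: expand to one row per class
            self.coef_ = np.vstack([-self.svc_.coef_[0], self.svc_.coef_[0]])
            self.intercept_ = np.array([-self.svc_.intercept_[0], self.svc_.intercept_[0]])
        else:
            self.coef_ = self.svc_.coef_
            self.intercept_ = self.svc_.intercept_
        return self

    def scale(self, X: np.ndarray) -> np.ndarray:
        """Apply the training-fitted min-max scaler (no clipping)."""
        check_is_fitted(self, "scaler_")
        return self.scaler_.transform(np.asarray(X, dtype=float))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "svc_")
        return self.scale(X) @ self.coef_.T + self.intercept_

    def predict(self, X: np.ndarray):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


def train_svm(train_X: np.ndarray, train_y, C: float, **kwargs) -> LinearStanceSVM:
    """Convenience wrapper: fit a :class:`LinearStanceSVM` at a fixed C."""
    return LinearStanceSVM(C=C, **kwargs).fit(train_X, train_y)


def zero_rule_baseline(train_y) -> float:
    """Accuracy of always predicting the modal training class.

    Ties between equally frequent classes are broken by the
    first-encountered label.
    """
    y = pd.Series(np.asarray(train_y))
    if y.empty:
        raise ValueError("labels must be non-empty")
    counts = y.value_counts(sort=False)  # preserves first-encounter order
    return counts.max() / len(y)


def make_folds(task: TaskSpec | str, metadata: pd.DataFrame, k: int = 4,
               seed: int = 0) -> np.ndarray:
    """Assign every recording to one of ``k`` outer folds under the task rule.

    * per-class-balanced: each (subject, footwear) cell's trials are dealt
      round-robin (with a random per-cell offset), so every cell contributes
      equal counts (+/-1) to every fold.
    * footwear-disjoint: each footwear condition's recordings form exactly
      one fold (requires k == number of conditions).
    * subject-disjoint: subjects are shuffled and partitioned into k groups
      of near-equal size; each group's recordings form one fold.
    """
    if isinstance(task, str):
        task = TASKS[task]
    rng = np.random.default_rng(seed)
    n = len(metadata)
    folds = np.full(n, -1, dtype=int)

    if task.fold_rule == "per-class-balanced":
        cells = metadata.groupby(["subject_id", "footwear_id"], sort=True).indices
        for idx in cells.values():
            idx = np.asarray(idx)
            order = rng.permutation(len(idx))
            offset = int(rng.integers(k))
            folds[idx[order]] = (np.arange(len(idx)) + offset) % k
    elif task.fold_rule == "footwear-disjoint":
        conditions = sorted(metadata["footwear_id"].unique())
        if len(conditions) != k:
            raise ValueError(
                f"footwear-disjoint folding needs k == n_conditions "
                f"({len(conditions)}), got k={k}"
            )
        assignment = dict(zip(rng.permutation(conditions), range(k)))
        folds[:] = metadata["footwear_id"].map(assignment).to_numpy()
    elif task.fold_rule == "subject-disjoint":
        subjects = np.array(sorted(metadata["subject_id"].unique()))
        if len(subjects) < k:
            raise ValueError(f"need at least k={k} subjects, got {len(subjects)}")
        groups = np.array_split(rng.permutation(subjects), k)
        assignment = {s: f for f, grp in enumerate(groups) for s in grp}
        folds[:] = metadata["subject_id"].map(assignment).to_numpy()
    else:  # pragma: no cover - TaskSpec is validated at construction sites
        raise ValueError(f"unknown fold rule {task.fold_rule!r}")
    return folds


def inner_splits(task: TaskSpec | str, metadata: pd.DataFrame, seed: int = 0
                 ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Two-fold inner splits of a training set, respecting the task rule.

    For the subject task an even footwear-disjoint two-fold split of the
    three training conditions is impossible; the closest analogue is used:
    one inner fold holds one condition, the other holds the remaining two,
    and both directions are evaluated and averaged.
    """
    if isinstance(task, str):
        task = TASKS[task]
    rng = np.random.default_rng(seed)
    n = len(metadata)
    half = np.zeros(n, dtype=int)

    if task.fold_rule == "per-class-balanced":
        cells = metadata.groupby(["subject_id", "footwear_id"], sort=True).indices
        for idx in cells.values():
            idx = np.asarray(idx)
            order = rng.permutation(len(idx))
            offset = int(rng.integers(2))
            half[idx[order]] = (np.arange(len(idx)) + offset) % 2
    elif task.fold_rule == "footwear-disjoint":
        conditions = rng.permutation(sorted(metadata["footwear_id"].unique()))
        lone = {conditions[0]}
        half[:] = np.where(metadata["footwear_id"].isin(lone), 0, 1)
    elif task.fold_rule == "subject-disjoint":
        subjects = np.array(sorted(metadata["subject_id"].unique()))
        groups = np.array_split(rng.permutation(subjects), 2)
        assignment = {s: f for f, grp in enumerate(groups) for s in grp}
        half[:] = metadata["subject_id"].map(assignment).to_numpy()
    else:  # pragma: no cover
        raise ValueError(f"unknown fold rule {task.fold_rule!r}")

    all_idx = np.arange(n)
    a, b = all_idx[half == 0], all_idx[half == 1]
    return [(b, a), (a, b)]  # (train, validate) in both directions


def grid_search_C(
    train_X: np.ndarray,
    train_y,
    grid: np.ndarray | None = None,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
    seed: int = 0,
    **svm_params,
) -> tuple[float, np.ndarray]:
    """Select C by mean accuracy over the inner splits; ties -> smallest C.

    Returns ``(best_C, mean_scores)`` with scores aligned to the grid.
    If no splits are given, a stratified-by-label two-fold split is built.
    """
    grid = c_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty C grid")
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    labels, counts = np.unique(train_y, return_counts=True)
    if labels.size < 2:
        raise ValueError("training data must contain at least 2 classes")
    if counts.min() < 2:
        raise ValueError("grid search needs at least 2 recordings per class")

    if splits is None:
        rng = np.random.default_rng(seed)
        half = np.zeros(len(train_y), dtype=int)
        for lab in labels:
            idx = np.flatnonzero(train_y == lab)
            order = rng.permutation(len(idx))
            half[idx[order]] = np.arange(len(idx)) % 2
        all_idx = np.arange(len(train_y))
        a, b = all_idx[half == 0], all_idx[half == 1]
        splits = [(b, a), (a, b)]

    scores = np.zeros(grid.size)
    for j, C in enumerate(grid):
        accs = []
        for tr, va in splits:
            model = LinearStanceSVM(C=C, **svm_params).fit(train_X[tr], train_y[tr])
            accs.append(float(np.mean(model.predict(train_X[va]) == train_y[va])))
        scores[j] = np.mean(accs)
    order = np.argsort(grid)  # smallest C wins ties
    best = order[int(np.argmax(scores[order]))]
    return float(grid[best]), scores


@dataclass
class CVReport:
    """Results of one task's outer cross-validation."""

    task: str
    fold_accuracies: list[float]
    selected_C: list[float]
    fold_baselines: list[float]  # zero-rule on each outer-train set
    class_baseline: float        # zero-rule on the full class structure
    confusion: pd.DataFrame      # rows true class, columns predicted
    per_subject_accuracy: pd.Series
    per_footwear_accuracy: pd.Series
    predictions: pd.DataFrame    # per recording: fold, y_true, y_pred
    folds: np.ndarray = field(repr=False)
    models: list[LinearStanceSVM] = field(repr=False, default_factory=list)

    @property
    def median_accuracy(self) -> float:
        return float(np.median(self.fold_accuracies))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def pooled_accuracy(self) -> float:
        return float((self.predictions["y_true"] == self.predictions["y_pred"]).mean())

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "fold_accuracies": self.fold_accuracies,
            "median_accuracy": self.median_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "pooled_accuracy": self.pooled_accuracy,
            "selected_C": self.selected_C,
            "fold_baselines": self.fold_baselines,
            "class_baseline": self.class_baseline,
            "per_subject_accuracy": self.per_subject_accuracy.to_dict(),
            "per_footwear_accuracy": self.per_footwear_accuracy.to_dict(),
        }


def run_task(
    features: np.ndarray,
    metadata: pd.DataFrame,
    task: TaskSpec | str,
    k: int = 4,
    seed: int = 0,
    grid: np.ndarray | None = None,
    tol: float = 1e-4,
    max_iter: int = 5000,
) -> CVReport:
    """Nested cross-validation for one task.

    Per outer fold: build task-aware inner splits of the training set, grid
    search C (scaler refitted within every inner fit), refit on the full
    outer-training set at the selected C, and predict the held-out fold.
    Scaling and tuning therefore never see test recordings.
    """
    if isinstance(task, str):
        task = TASKS[task]
    features = np.asarray(features, dtype=float)
    y = task.label_fn(metadata).to_numpy()
    folds = make_folds(task, metadata, k=k, seed=seed)

    fold_accs: list[float] = []
    selected: list[float] = []
    baselines: list[float] = []
    models: list[LinearStanceSVM] = []
    y_pred = np.empty(len(y), dtype=object)

    for f in range(k):
        train_idx = np.flatnonzero(folds != f)
        test_idx = np.flatnonzero(folds == f)
        meta_train = metadata.iloc[train_idx].reset_index(drop=True)
        splits = inner_splits(task, meta_train, seed=seed + f)
        C, _ = grid_search_C(
            features[train_idx], y[train_idx], grid=grid, splits=splits,
            tol=tol, max_iter=max_iter, random_state=seed,
        )
        model = LinearStanceSVM(C=C, tol=tol, max_iter=max_iter, random_state=seed)
        model.fit(features[train_idx], y[train_idx])
        pred = model.predict(features[test_idx])
        y_pred[test_idx] = pred
        fold_accs.append(float(np.mean(pred == y[test_idx])))
        selected.append(C)
        baselines.append(zero_rule_baseline(y[train_idx]))
        models.append(model)

    predictions = pd.DataFrame(
        {
            "fold": folds,
            "subject_id": metadata["subject_id"].to_numpy(),
            "footwear_id": metadata["footwear_id"].to_numpy(),
            "y_true": y,
            "y_pred": y_pred.astype(str),
        }
    )
    classes = sorted(pd.unique(pd.Series(y)))
    confusion = (
        pd.crosstab(predictions["y_true"], predictions["y_pred"])
        .reindex(index=classes, columns=classes, fill_value=0)
    )
    correct = predictions["y_true"] == predictions["y_pred"]
    per_subject = correct.groupby(predictions["subject_id"]).mean()
    per_footwear = correct.groupby(predictions["footwear_id"]).mean()

    return CVReport(
        task=task.name,
        fold_accuracies=fold_accs,
        selected_C=selected,
        fold_baselines=baselines,
        class_baseline=zero_rule_baseline(y),
        confusion=confusion,
        per_subject_accuracy=per_subject,
        per_footwear_accuracy=per_footwear,
        predictions=predictions,
        folds=folds,
        models=models,
    )
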