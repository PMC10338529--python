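"""Relevance decomposition of linear-SVM predictions (LRP for linear models).

For a linear one-vs-rest classifier the relevance of input i to class k is
simply ``R_i = x_i * w_{k,i}``, where x is the min-max-scaled input vector
and w_k the class-k weight vector; the bias is not distributed onto inputs.
Explanations are computed for the ground-truth class of each recording.
Following common practice for comparing explanations across trials, only
positive relevance is analysed, each trial's scores are normalised to their
own maximum, and normalised maps are summed per time point and per force
channel across a grouping (whole task, class, or subject).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CVReport, LinearStanceSVM
from .preprocess import N_POINTS

__all__ = [
    "RelevanceAggregate",
    "decompose",
    "positive_normalize",
    "decompose_cv",
    "aggregate",
]

CHANNELS = ("ml", "ap", "v")


def decompose(
    model: LinearStanceSVM,
    X: np.ndarray,
    y_true,
    assume_scaled: bool = False,
) -> np.ndarray:
    """Raw relevance scores R = x_scaled * w_true_class, row-wise.

    ``X`` is (n, n_features) of unscaled features by default; the model's
    own training scaler is applied first. The algebraic identity
    ``sum_i R_i = decision_score(true class) - intercept`` holds exactly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xs = X if assume_scaled else model.scale(X)
    y_true = np.asarray(y_true)
    class_index = {c: i for i, c in enumerate(model.classes_)}
    try:
        rows = np.array([class_index[c] for c in y_true])
    except KeyError as err:
        raise ValueError(f"unknown class label: {err.args[0]!r}") from None
    return Xs * model.coef_[rows]


def positive_normalize(R: np.ndarray) -> np.ndarray:
    """Keep positive scores and scale each map to its own maximum.

    Negative relevance is zeroed; each row is divided by its maximum
    positive score, so the largest surviving score is exactly 1. Rows with
    no positive score come back all-zero.
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    pos = np.where(R > 0, R, 0.0)
    peak = pos.max(axis=1, keepdims=True)
    out = np.divide(pos, peak, out=np.zeros_like(pos), where=peak > 0)
    return out if np.asarray(R).ndim == 2 else out[0]


def decompose_cv(
    report: CVReport,
    features: np.ndarray,
    normalize: bool = True,
) -> np.ndarray:
    """Relevance maps for every recording, using its test-fold model.

    Each recording is decomposed by the model of the outer fold in which it
    was a test sample (so explanations describe unseen-data predictions),
    for its ground-truth class. Returns (n_recordings, n_features).
    """
    features = np.asarray(features, dtype=float)
    y = report.predictions["y_true"].to_numpy()
    R = np.zeros_like(features)
    for f, model in enumerate(report.models):
        idx = np.flatnonzero(report.folds == f)
        R[idx] = decompose(model, features[idx], y[idx])
    return positive_normalize(R) if normalize else R


@dataclass(frozen=True)
class RelevanceAggregate:
    """Summed relevance for one group: per time point and per channel."""

    group: str
    per_timepoint: np.ndarray   # (3, n_points), channel order ML, AP, V
    channel_totals: np.ndarray  # (3,)
    mean_curves: np.ndarray     # (3, n_points) mean input curves of the group
    n_maps: int

    def channel_share(self) -> pd.Series:
        """Fraction of total relevance per channel."""
        total = self.channel_totals.sum()
        share = self.channel_totals / total if total > 0 else np.zeros(3)
        return pd.Series(share, index=list(CHANNELS))


def aggregate(
    R: np.ndarray,
    metadata: pd.DataFrame | None = None,
    group_by: str = "task",
    features: np.ndarray | None = None,
    n_points: int = N_POINTS,
) -> dict[str, RelevanceAggregate]:
    """Sum relevance maps per time point and channel, within groups.

    ``group_by`` is "task" (one aggregate over all maps), "class"
    (per footwear condition) or "subject". ``features`` (unscaled curves)
    optionally provides mean input curves for colour-coded plotting exports.
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if R.shape[0] == 0:
        raise ValueError("cannot aggregate an empty set of relevance maps")
    if R.shape[1] != 3 * n_points:
        raise ValueError(f"expected {3 * n_points} columns, got {R.shape[1]}")
    if group_by == "task":
        keys = pd.Series(["all"] * len(R))
    elif group_by == "class":
        keys = metadata["footwear_id"].astype(str).reset_index(drop=True)
    elif group_by == "subject":
        keys = metadata["subject_id"].astype(str).reset_index(drop=True)
    else:
        raise ValueError(f"unknown group_by {group_by!r}")

    out: dict[str, RelevanceAggregate] = {}
    for key, idx in keys.groupby(keys).groups.items():
        idx = np.asarray(idx)
        if idx.size == 0:
            raise ValueError(f"empty group {key!r}")
        summed = R[idx].sum(axis=0).reshape(3, n_points)
        if features is not None:
            mean_curves = np.asarray(features, dtype=float)[idx].mean(axis=0).reshape(3, n_points)
        else:
            mean_curves = np.full((3, n_points), np.nan)
        out[str(key)] = RelevanceAggregate(
            group=str(key),
            per_timepoint=summed,
            channel_totals=summed.sum(axis=1),
            mean_curves=mean_curves,
            n_maps=int(idx.size),
        )
    return out
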