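"""Raw force traces -> 101-point body-weight-normalised stance curves.

The processing chain mirrors standard force-plate practice: zero-phase
low-pass filtering (2nd-order Butterworth applied forward and backward,
50 Hz cut-off), stance detection on the filtered vertical force with a 10 N
threshold, time normalisation of each channel to 101 points (0-100 %stance),
and normalisation to body weight measured per footwear condition (%BW).
Feature vectors for classification are the three curves concatenated in the
fixed order ML || AP || V (303 values); min-max scaling to [0, 1] is fitted
on training data only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.preprocessing import MinMaxScaler
from sklearn.utils.validation import check_is_fitted

from .synthetic import ForceRecording

__all__ = [
    "StanceCurves",
    "lowpass_filter",
    "detect_stance",
    "time_normalize",
    "normalize_body_weight",
    "build_feature_vector",
    "fit_minmax",
    "apply_minmax",
    "process_recording",
    "process_dataset",
    "N_POINTS",
    "N_FEATURES",
]

N_POINTS = 101
N_FEATURES = 3 * N_POINTS


@dataclass(frozen=True)
class StanceCurves:
    """Filtered, stance-cropped, time- and body-weight-normalised curves."""

    ml: np.ndarray  # %BW, length n_points
    ap: np.ndarray
    v: np.ndarray
    stance_duration_ms: float
    subject_id: int
    footwear_id: str
    trial_id: int

    def __post_init__(self) -> None:
        for name in ("ml", "ap", "v"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"{name} must be one-dimensional")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, arr)
        if not (len(self.ml) == len(self.ap) == len(self.v)):
            raise ValueError("channels must have equal length")


def lowpass_filter(
    samples: np.ndarray,
    sampling_rate: float,
    cutoff: float = 50.0,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter, applied per channel.

    The filter is designed at ``order`` and run forward and backward
    (bidirectional), which squares the magnitude response and cancels the
    phase. Edges are handled by reflective padding of length 3 x order; no
    cut-off correction for the double pass is applied.
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    if x.shape[0] == 1 and np.asarray(samples).ndim == 1:
        x = x.T
    if sampling_rate <= 2.0 * cutoff:
        raise ValueError("sampling_rate must exceed twice the cut-off frequency")
    padlen = 3 * order
    if x.shape[0] <= padlen:
        raise ValueError(
            f"input too short for filtering: need more than {padlen} samples, got {x.shape[0]}"
        )
    b, a = signal.butter(order, cutoff / (sampling_rate / 2.0), btype="low")
    y = signal.filtfilt(b, a, x, axis=0, padtype="even", padlen=padlen)
    return y[:, 0] if np.asarray(samples).ndim == 1 else y


def detect_stance(v_filtered: np.ndarray, threshold: float = 10.0) -> tuple[int, int]:
    """Locate the stance phase on the filtered vertical force.

    Returns the half-open index range ``[start, end)`` of the longest maximal
    contiguous run of samples strictly above ``threshold`` (ties broken by
    the earliest run). Raises ``ValueError`` if no sample exceeds the
    threshold.
    """
    v = np.asarray(v_filtered, dtype=float)
    above = v > threshold
    if not above.any():
        raise ValueError(f"no stance detected: no sample above {threshold} N")
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(v)]
    lengths = ends - starts
    best = int(np.argmax(lengths))  # argmax takes the first maximal run
    return int(starts[best]), int(ends[best])


def time_normalize(segment: np.ndarray, n_points: int = N_POINTS) -> np.ndarray:
    """Piecewise-linear resampling onto ``n_points`` evenly spaced abscissae.

    The output grid spans the first to the last input sample, so the
    endpoints are preserved exactly.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim == 1:
        if seg.size < 2:
            raise ValueError("segment must contain at least 2 samples")
        grid = np.linspace(0.0, seg.size - 1.0, n_points)
        return np.interp(grid, np.arange(seg.size), seg)
    return np.column_stack([time_normalize(seg[:, c], n_points) for c in range(seg.shape[1])])


def normalize_body_weight(curves: np.ndarray, body_weight_n: float) -> np.ndarray:
    """Convert forces in N to percent body weight (%BW)."""
    if body_weight_n <= 0:
        raise ValueError("body_weight_n must be positive")
    return np.asarray(curves, dtype=float) * (100.0 / body_weight_n)


def build_feature_vector(stance: StanceCurves, n_points: int = N_POINTS) -> np.ndarray:
    """Concatenate the three curves in fixed order ML || AP || V."""
    if len(stance.ml) != n_points:
        raise ValueError(f"expected {n_points}-point curves, got {len(stance.ml)}")
    return np.concatenate([stance.ml, stance.ap, stance.v])


def fit_minmax(training_vectors: np.ndarray) -> MinMaxScaler:
    """Fit the per-input min-max scaler on training-set vectors only.

    Inputs that are constant across the training set map to 0 after scaling
    (degenerate-range rule). Test values outside the training range are not
    clipped.
    """
    X = np.asarray(training_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_minmax needs a 2-D array with at least 2 vectors")
    return MinMaxScaler(clip=False).fit(X)


def apply_minmax(scaler: MinMaxScaler, vectors: np.ndarray) -> np.ndarray:
    check_is_fitted(scaler)
    return scaler.transform(np.atleast_2d(np.asarray(vectors, dtype=float)))


def process_recording(
    rec: ForceRecording,
    cutoff: float = 50.0,
    threshold: float = 10.0,
    n_points: int = N_POINTS,
) -> StanceCurves:
    """Filter, crop to stance, time-normalise and %BW-normalise one recording."""
    filtered = lowpass_filter(rec.samples, rec.sampling_rate, cutoff=cutoff)
    start, end = detect_stance(filtered[:, 2], threshold=threshold)
    stance = time_normalize(filtered[start:end], n_points)
    stance = normalize_body_weight(stance, rec.body_weight_n)
    return StanceCurves(
        ml=stance[:, 0],
        ap=stance[:, 1],
        v=stance[:, 2],
        stance_duration_ms=(end - start) / rec.sampling_rate * 1000.0,
        subject_id=rec.subject_id,
        footwear_id=rec.footwear_id,
        trial_id=rec.trial_id,
    )


def process_dataset(
    recordings: list[ForceRecording],
    cutoff: float = 50.0,
    threshold: float = 10.0,
    n_points: int = N_POINTS,
) -> tuple[np.ndarray, list[StanceCurves], pd.DataFrame]:
    """Process every recording; returns (features, curves, metadata).

    ``features`` is the unscaled (n_recordings, 3 x n_points) matrix; scaling
    to [0, 1] happens later, inside each cross-validation fold, on training
    data only.
    """
    curves = [process_recording(r, cutoff, threshold, n_points) for r in recordings]
    features = np.vstack([build_feature_vector(c, n_points) for c in curves])
    meta = pd.DataFrame(
        {
            "subject_id": [c.subject_id for c in curves],
            "footwear_id": [c.footwear_id for c in curves],
            "trial_id": [c.trial_id for c in curves],
            "stance_duration_ms": [c.stance_duration_ms for c in curves],
        }
    )
    return features, curves, meta
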