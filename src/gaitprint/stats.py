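"""Statistical evaluation of footwear effects on the stance curves.

Two complementary analyses:

* Time-continuous: a pointwise one-way ANOVA across footwear conditions at
  each of the 101 stance time points, with family-wise error control over
  the whole curve by permutation of condition labels (the null distribution
  of the maximum F over time points yields the critical threshold F*;
  contiguous supra-threshold runs are reported as significant clusters).
  This is the permutation flavour of 1-D statistical parametric mapping.
* Time-discrete: classical peak variables per recording (vertical impact and
  active peaks, AP braking/propulsion peaks, ML extrema — magnitude and
  timing), compared across conditions with a Kruskal-Wallis test and, when
  significant, pairwise Dwass-Steel-Critchlow-Fligner post-hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import StanceCurves

__all__ = [
    "SPMResult",
    "DiscreteVariables",
    "spm_anova",
    "extract_discrete",
    "discrete_table",
    "kruskal_wallis",
    "dscf_posthoc",
    "evaluate_discrete",
]


@dataclass(frozen=True)
class SPMResult:
    """Permutation-SPM one-way ANOVA along the stance phase."""

    f_values: np.ndarray                 # (n_points,)
    f_critical: float                    # permutation max-F threshold
    clusters: list[tuple[int, int]]      # inclusive (%stance start, end)
    alpha: float
    n_perm: int

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0


def _pointwise_f(Y: np.ndarray, G: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """One-way ANOVA F at each column of Y, groups encoded by indicator G."""
    n, k = G.shape
    means = (G.T @ Y) / counts[:, None]                 # (k, n_points)
    grand = Y.mean(axis=0)
    ssb = (counts[:, None] * (means - grand) ** 2).sum(axis=0)
    ssw = (Y**2).sum(axis=0) - (counts[:, None] * means**2).sum(axis=0)
    ssw = np.maximum(ssw, 1e-300)
    return (ssb / (k - 1)) / (ssw / (n - k))


def spm_anova(
    curves: np.ndarray,
    groups,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> SPMResult:
    """One-way ANOVA over a family of 1-D curves with max-F permutation FWER.

    ``curves`` is (n_curves, n_points); ``groups`` assigns each curve to a
    condition. The critical threshold F* is the (1 - alpha) quantile (upper
    order statistic) of the permutation distribution of max-over-time F,
    with the observed labelling included as one permutation; clusters are
    maximal contiguous runs with F > F*.
    """
    Y = np.asarray(curves, dtype=float)
    if Y.ndim != 2:
        raise ValueError("curves must be 2-D (n_curves, n_points)")
    labels, inverse = np.unique(np.asarray(groups), return_inverse=True)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(inverse)
    if counts.min() < 2:
        raise ValueError("need at least 2 curves per group")
    if len(inverse) != Y.shape[0]:
        raise ValueError("groups length must match number of curves")

    n, k = Y.shape[0], labels.size
    G = np.zeros((n, k))
    G[np.arange(n), inverse] = 1.0
    f_obs = _pointwise_f(Y, G, counts)

    rng = np.random.default_rng(seed)
    max_f = np.empty(n_perm)
    max_f[0] = f_obs.max()  # identity permutation included
    for p in range(1, n_perm):
        perm = rng.permutation(n)
        max_f[p] = _pointwise_f(Y[perm], G, counts).max()
    f_crit = float(np.quantile(max_f, 1.0 - alpha, method="higher"))

    above = f_obs > f_crit
    clusters: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            clusters.append((start, i - 1))
            start = None
    if start is not None:
        clusters.append((start, len(above) - 1))

    return SPMResult(f_values=f_obs, f_critical=f_crit, clusters=clusters,
                     alpha=alpha, n_perm=n_perm)


@dataclass(frozen=True)
class DiscreteVariables:
    """Classical peak variables of one stance (magnitudes %BW, times %stance).

    The vertical impact peak is the first local maximum within the first
    third of stance; it can be absent (e.g. midfoot/forefoot-like curves),
    in which case both its fields are None. The active peak is the global
    maximum after the impact peak (or overall when no impact peak exists).
    AP braking is the global minimum in (0, 50] %stance, propulsion the
    global maximum in (50, 100) %stance; ML max/min are global extrema.
    Ties resolve to the earliest index.
    """

    impact_peak_bw: float | None
    impact_time_pct: float | None
    active_peak_bw: float
    active_time_pct: float
    braking_peak_bw: float
    braking_time_pct: float
    propulsion_peak_bw: float
    propulsion_time_pct: float
    ml_max_bw: float
    ml_max_time_pct: float
    ml_min_bw: float
    ml_min_time_pct: float


def _first_local_max(v: np.ndarray, lo: int, hi: int) -> int | None:
    """Earliest interior local maximum (strict rise, non-strict fall) in [lo, hi]."""
    for i in range(max(lo, 1), min(hi, len(v) - 2) + 1):
        if v[i] > v[i - 1] and v[i] >= v[i + 1]:
            return i
    return None


def extract_discrete(stance: StanceCurves) -> DiscreteVariables:
    """Extract the time-discrete peak variables from one 101-point stance."""
    v, ap, ml = stance.v, stance.ap, stance.ml
    n = len(v)
    pct = 100.0 / (n - 1)

    third = int(round(33 / pct))
    i_imp = _first_local_max(v, 1, third)
    lo = (i_imp + 1) if i_imp is not None else 0
    i_act = lo + int(np.argmax(v[lo : n - 1])) if lo < n - 1 else n - 1
    if i_imp is None:
        i_act = int(np.argmax(v))

    half = int(round(50 / pct))
    i_br = 1 + int(np.argmin(ap[1 : half + 1]))
    i_pr = half + 1 + int(np.argmax(ap[half + 1 : n - 1]))

    i_ml_max = int(np.argmax(ml))
    i_ml_min = int(np.argmin(ml))

    return DiscreteVariables(
        impact_peak_bw=float(v[i_imp]) if i_imp is not None else None,
        impact_time_pct=i_imp * pct if i_imp is not None else None,
        active_peak_bw=float(v[i_act]),
        active_time_pct=i_act * pct,
        braking_peak_bw=float(ap[i_br]),
        braking_time_pct=i_br * pct,
        propulsion_peak_bw=float(ap[i_pr]),
        propulsion_time_pct=i_pr * pct,
        ml_max_bw=float(ml[i_ml_max]),
        ml_max_time_pct=i_ml_max * pct,
        ml_min_bw=float(ml[i_ml_min]),
        ml_min_time_pct=i_ml_min * pct,
    )


def discrete_table(curves: list[StanceCurves]) -> pd.DataFrame:
    """Discrete variables for a set of stances, one row per recording."""
    rows = []
    for c in curves:
        d = extract_discrete(c)
        rows.append(
            {"subject_id": c.subject_id, "footwear_id": c.footwear_id,
             "trial_id": c.trial_id, **d.__dict__}
        )
    return pd.DataFrame(rows)


def kruskal_wallis(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-squared p across groups.

    All-identical values return (H=0, p=1) rather than an error.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs at least 1 value")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def _pair_dscf(a: np.ndarray, b: np.ndarray, k: int) -> float:
    """DSCF p-value for one pair: pairwise Wilcoxon rank sum referred to the
    studentized-range distribution with k groups (infinite df)."""
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w_b = ranks[n_a:].sum()
    n = n_a + n_b
    expect = n_b * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (w_b - expect) / np.sqrt(var)
    q = np.sqrt(2.0) * abs(z)
    return float(sps.studentized_range.sf(q, k, np.inf))


def dscf_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Dwass-Steel-Critchlow-Fligner p-values.

    For each pair, ranks are computed on that pair only; the standardized
    rank-sum statistic is referred to the studentized-range distribution
    with k groups. The table is symmetric with NaN on the diagonal; pairs
    involving a group with fewer than 2 values are left NaN (untestable).
    """
    names = list(groups.keys())
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 groups")
    table = pd.DataFrame(np.nan, index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            a = np.asarray(groups[names[i]], dtype=float)
            b = np.asarray(groups[names[j]], dtype=float)
            if len(a) < 2 or len(b) < 2:
                continue
            p = _pair_dscf(a, b, k)
            table.iloc[i, j] = p
            table.iloc[j, i] = p
    return table


def evaluate_discrete(
    table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Kruskal-Wallis per discrete variable across footwear, with DSCF post-hoc.

    Returns one row per variable: H, p, significance flag, and (when
    significant) the pairwise DSCF p-values as a nested dict. Recordings
    with a missing impact peak are dropped for the impact-peak variables.
    """
    variables = [c for c in table.columns
                 if c not in ("subject_id", "footwear_id", "trial_id")]
    rows = []
    for var in variables:
        sub = table[["footwear_id", var]].dropna()
        groups = {
            str(cond): grp[var].to_numpy()
            for cond, grp in sub.groupby("footwear_id", sort=True)
        }
        if len(groups) < 2:
            continue
        h, p = kruskal_wallis(groups)
        row = {"variable": var, "H": h, "p": p, "significant": p < alpha}
        if p < alpha:
            dscf = dscf_posthoc(groups)
            row["dscf"] = {
                f"{a} vs {b}": float(dscf.loc[a, b])
                for ai, a in enumerate(dscf.index)
                for b in dscf.columns[ai + 1 :]
                if np.isfinite(dscf.loc[a, b])
            }
        rows.append(row)
    return pd.DataFrame(rows)
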