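"""Regression evaluation: MAE, RMSE, Pearson r, fold aggregation, histogram intersection.

MAE and RMSE are reported in the units of the trait (kg/ha here); r is the
standard Pearson product-moment correlation. Histogram intersection compares
the distributions of observed and predicted values as the summed bin-wise
minimum of the two proportion histograms over shared edges; the number of bins
can be chosen by an elbow rule on the within-bin sum of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class MetricSet:
    n: int
    mae: float
    rmse: float
    r: float  # NaN when undefined (degenerate variance)
    r_defined: bool = True


@dataclass(frozen=True)
class FoldSummary:
    mean: dict[str, float]
    sd: dict[str, float | None]  # None at a single fold (sd undefined, ddof=1)
    n_folds: int


def regression_metrics(y, yhat) -> MetricSet:
    """MAE, RMSE and Pearson r between observed and predicted vectors.

    A zero-variance input makes r undefined; it is returned as NaN with
    ``r_defined=False`` and a warning, never silently as 0.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError(f"y and yhat must be equal-length 1-d vectors, got {y.shape}, {yhat.shape}")
    if not (np.isfinite(y).all() and np.isfinite(yhat).all()):
        raise ValueError("inputs must be finite")
    err = y - yhat
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if len(y) < 2 or np.ptp(y) == 0 or np.ptp(yhat) == 0:
        warnings.warn("Pearson r undefined (degenerate variance or n < 2)", stacklevel=2)
        return MetricSet(len(y), mae, rmse, float("nan"), r_defined=False)
    r = float(stats.pearsonr(y, yhat).statistic)
    return MetricSet(len(y), mae, rmse, r)


def aggregate_folds(sets: list[MetricSet]) -> FoldSummary:
    """Unweighted across-fold mean and sample sd (ddof=1) of each metric."""
    if not sets:
        raise ValueError("no folds to aggregate")
    out_mean: dict[str, float] = {}
    out_sd: dict[str, float | None] = {}
    for name in ("mae", "rmse", "r"):
        vals = np.array([getattr(s, name) for s in sets], dtype=float)
        out_mean[name] = float(np.nanmean(vals))
        out_sd[name] = float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else None
    return FoldSummary(out_mean, out_sd, len(sets))


def histogram_intersection(y, yhat, n_bins: int = 20, edges: str = "union") -> float:
    """Intersection area of the proportion histograms of y and yhat.

    Shared bin edges span the union of both ranges (``edges="union"``, the
    symmetric convention) or the range of y alone (``edges="real_only"``, in
    which predicted values outside the range fall in no bin). Proportions
    normalize by each vector's length, so unequal lengths are admissible;
    the result lies in [0, 1].
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0 or yhat.size == 0:
        raise ValueError("inputs must be non-empty")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if edges == "union":
        lo = min(y.min(), yhat.min())
        hi = max(y.max(), yhat.max())
    elif edges == "real_only":
        lo, hi = y.min(), y.max()
    else:
        raise ValueError(f"edges must be 'union' or 'real_only', got {edges!r}")
    if lo == hi:  # all mass in one degenerate bin
        hi = lo + 1.0
    bin_edges = np.linspace(lo, hi, n_bins + 1)
    p = np.histogram(y, bins=bin_edges)[0] / y.size
    q = np.histogram(yhat, bins=bin_edges)[0] / yhat.size
    return float(np.minimum(p, q).sum())


def elbow_bins(y, candidates=range(5, 41)) -> int:
    """Pick a bin count by the elbow of the within-bin sum-of-squares curve.

    For each candidate k, y is binned into k equal-width bins and scored by the
    within-bin sum of squared deviations from bin means (representativeness of
    the binned distribution). The elbow is the candidate farthest from the
    chord joining the normalized score curve's endpoints — beyond it, extra
    bins no longer buy representativeness.
    """
    y = np.asarray(y, dtype=float)
    cand = sorted(set(int(k) for k in candidates))
    if not cand:
        raise ValueError("candidate range is empty")
    n_distinct = len(np.unique(y))
    if n_distinct <= 1:
        return 1
    if cand[-1] > n_distinct:
        warnings.warn(f"capping candidate bins at {n_distinct} distinct values", stacklevel=2)
        cand = [k for k in cand if k <= n_distinct] or [n_distinct]
    if len(cand) == 1:
        return cand[0]

    def wss(k: int) -> float:
        edges = np.linspace(y.min(), y.max(), k + 1)
        idx = np.clip(np.digitize(y, edges[1:-1]), 0, k - 1)
        total = 0.0
        for b in range(k):
            vals = y[idx == b]
            if vals.size:
                total += float(((vals - vals.mean()) ** 2).sum())
        return total

    scores = np.array([wss(k) for k in cand])
    if scores[0] <= 0:
        return cand[0]
    s = scores / scores[0]  # scale by the first candidate only, so the choice
    # does not move when the candidate range is extended upward
    if len(s) < 3:
        return cand[int(np.argmin(s))]
    curvature = s[:-2] - 2 * s[1:-1] + s[2:]  # discrete second difference
    return cand[1 + int(np.argmax(curvature))]
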