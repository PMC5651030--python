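"""Whole-brain connectivity metrics from ROI time series.

Three metrics are supported, each producing one N x N matrix "channel":

* Pearson correlation — classical static connectivity strength.
* Dynamic Time Warping (DTW) distance — accumulated cost of the optimal
  monotonic alignment of two z-scored BOLD signals; robust to slowly
  drifting phase relationships between regions.
* Warping path length — the number of cells in the optimal alignment
  path. Identical series need no warping (path length T); unstable
  phase relationships force many non-diagonal steps and longer paths,
  so path length measures connection (phase) stability, complementing
  the distance.

DTW uses the step set {(1,0), (0,1), (1,1)} restricted to a Sakoe–Chiba
band of configurable half-width, and recovers one optimal path by
backtracking with diagonal-preferred tie-breaking (which yields the
shortest path among cost-optimal ones in the common cases and makes the
path length deterministic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TimeSeriesSet",
    "DtwParams",
    "DtwResult",
    "pearson_matrix",
    "dtw_pair",
    "dtw_matrices",
]


@dataclass
class TimeSeriesSet:
    """ROI time series: ``signals`` is time x ROI (T x N)."""

    signals: np.ndarray
    sampling_interval: float = 3.0
    roi_names: list | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-d (time x ROI) array")
        if self.signals.shape[0] < 2:
            raise ValueError("need at least 2 time points")
        if not np.isfinite(self.signals).all():
            raise ValueError("signals contain missing or non-finite values")
        if self.roi_names is not None and len(self.roi_names) != self.signals.shape[1]:
            raise ValueError("roi_names length does not match number of ROIs")

    @property
    def n_timepoints(self) -> int:
        return self.signals.shape[0]

    @property
    def n_rois(self) -> int:
        return self.signals.shape[1]


@dataclass
class DtwParams:
    """DTW configuration.

    ``window_radius`` is the Sakoe–Chiba band half-width in samples;
    ``None`` means the default ceil(T/10). ``local_cost`` is the
    per-cell cost: absolute or squared difference. With ``znormalize``
    each series is z-scored before alignment (constant series then
    raise, as their z-score is undefined).
    """

    window_radius: int | None = None
    local_cost: str = "absolute"
    znormalize: bool = True

    def __post_init__(self) -> None:
        if self.local_cost not in ("absolute", "squared"):
            raise ValueError("local_cost must be 'absolute' or 'squared'")
        if self.window_radius is not None and self.window_radius < 0:
            raise ValueError("window_radius must be >= 0")

    def effective_radius(self, n_timepoints: int) -> int:
        r = self.window_radius
        if r is None:
            r = math.ceil(n_timepoints / 10)
        return min(r, n_timepoints - 1)


@dataclass
class DtwResult:
    """Distance, path length L (T <= L <= 2T-1) and (L-T)/T."""

    distance: float
    path_length: int
    relative_path_length: float


def _znorm(x: np.ndarray, label: str) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError(f"cannot z-normalize constant series ({label})")
    return (x - x.mean()) / sd


def pearson_matrix(ts: TimeSeriesSet) -> np.ndarray:
    """Pearson correlation between every pair of ROI signals.

    Symmetric with unit diagonal, entries in [-1, 1]. Raises if any ROI
    signal has zero variance, naming the offending ROI.
    """
    sds = ts.signals.std(axis=0)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        name = ts.roi_names[bad[0]] if ts.roi_names else f"index {bad[0]}"
        raise ValueError(f"zero-variance signal for ROI {name}")
    corr = np.corrcoef(ts.signals.T)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def dtw_pair(x, y, params: DtwParams | None = None) -> DtwResult:
    """Banded DTW between two equal-length series.

    Dynamic program over the Sakoe–Chiba band with steps
    {(1,0), (0,1), (1,1)}; the distance is the raw accumulated local
    cost (no path-length normalization) and the path length is taken
    from one optimal path recovered by diagonal-preferred backtracking.
    """
    params = params or DtwParams()
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"series lengths differ: {x.size} vs {y.size}")
    t = x.size
    if t < 2:
        raise ValueError("series must have at least 2 samples")
    if params.znormalize:
        x = _znorm(x, "x")
        y = _znorm(y, "y")
    r = params.effective_radius(t)

    if params.local_cost == "absolute":
        cost = np.abs(x[:, None] - y[None, :])
    else:
        cost = (x[:, None] - y[None, :]) ** 2

    acc = np.full((t + 1, t + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, t + 1):
        lo = max(1, i - r)
        hi = min(t, i + r)
        for j in range(lo, hi + 1):
            best = min(acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1])
            acc[i, j] = cost[i - 1, j - 1] + best

    # backtrack one optimal path, preferring the diagonal on ties
    i, j = t, t
    length = 1
    while (i, j) != (1, 1):
        diag, up, left = acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]
        best = min(diag, up, left)
        if diag == best:
            i, j = i - 1, j - 1
        elif up == best:
            i = i - 1
        else:
            j = j - 1
        length += 1

    distance = float(acc[t, t])
    return DtwResult(
        distance=distance,
        path_length=length,
        relative_path_length=(length - t) / t,
    )


def dtw_matrices(
    ts: TimeSeriesSet,
    params: DtwParams | None = None,
    relative_path_length: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """DTW distance and warping-path-length matrices over all ROI pairs.

    Both outputs are symmetric (the symmetric step set makes DTW a
    symmetric function of its arguments). The distance diagonal is 0;
    the path-length diagonal is 0 in relative form (raw form: T).
    ``relative_path_length`` selects which form fills the second matrix.
    """
    params = params or DtwParams()
    n = ts.n_rois
    t = ts.n_timepoints
    dist = np.zeros((n, n))
    path = np.zeros((n, n))
    if not relative_path_length:
        np.fill_diagonal(path, t)
    for i in range(n):
        for j in range(i + 1, n):
            res = dtw_pair(ts.signals[:, i], ts.signals[:, j], params)
            dist[i, j] = dist[j, i] = res.distance
            val = res.relative_path_length if relative_path_length else res.path_length
            path[i, j] = path[j, i] = val
    return dist, path
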