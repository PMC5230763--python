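"""The "Change-of-Heart" (COH) detector.

Normalized resting heart rate is smoothed with a centered moving-average
filter and local maxima of the smoothed signal are called as abnormal
periods when they clear both a height and a prominence threshold of 2 z
units, with a minimum 3-h separation between retained peaks.  The
hyperparameters (3-h span, height 2, prominence 2, distance = span) are the
frozen defaults of the method.

Gap policy: stretches separated by more than ``max_bridge_gap_minutes`` of
missing data are smoothed and peak-called independently, so no signal is
fabricated across long absences.  Within a stretch, absent minutes are
simply omitted from the window mean.  At the edges of a stretch the window
shrinks symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._errors import ValidationError


@dataclass
class CohParams:
    """Hyperparameters of the COH peak caller (z units / minutes)."""

    span_minutes: int = 180
    min_peak_height: float = 2.0
    min_peak_distance_minutes: int = 180
    min_peak_prominence: float = 2.0
    max_bridge_gap_minutes: int = 180

    def __post_init__(self):
        for name in ("span_minutes", "min_peak_height", "min_peak_distance_minutes",
                     "min_peak_prominence", "max_bridge_gap_minutes"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    @property
    def span_odd(self) -> int:
        # even spans are widened by one for a symmetric center window
        span = int(self.span_minutes)
        return span if span % 2 == 1 else span + 1


@dataclass(frozen=True)
class Peak:
    """One COH detection on the smoothed z signal."""

    time: pd.Timestamp
    height: float
    prominence: float
    left_base: pd.Timestamp
    right_base: pd.Timestamp


def _run_bounds(index: pd.DatetimeIndex, max_gap_minutes: float):
    """Slices of ``index`` split where consecutive samples are > max_gap apart."""
    if len(index) == 0:
        return []
    gaps = np.diff(index.asi8) > max_gap_minutes * 60_000_000_000
    breaks = np.nonzero(gaps)[0] + 1
    edges = np.concatenate([[0], breaks, [len(index)]])
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def moving_average_smooth(z: pd.Series, params: CohParams | None = None) -> pd.Series:
    """Centered moving mean over ``span_minutes`` on the minute grid.

    Returns the smoothed value at every present minute; absent minutes stay
    absent.  See the module docstring for edge and gap conventions.
    """
    params = params or CohParams()
    if len(z) == 0:
        return pd.Series(dtype=float)
    half = params.span_odd // 2
    pieces = []
    for run in _run_bounds(z.index, params.max_bridge_gap_minutes):
        chunk = z.iloc[run]
        grid = pd.date_range(chunk.index[0], chunk.index[-1], freq="min")
        vals = chunk.reindex(grid)
        present = vals.notna().to_numpy()
        filled = np.nan_to_num(vals.to_numpy())
        csum = np.concatenate([[0.0], np.cumsum(filled)])
        ccnt = np.concatenate([[0], np.cumsum(present.astype(np.int64))])
        n = len(grid)
        i = np.arange(n)
        h = np.minimum(half, np.minimum(i, n - 1 - i))
        lo, hi = i - h, i + h + 1
        counts = ccnt[hi] - ccnt[lo]
        with np.errstate(invalid="ignore"):
            means = (csum[hi] - csum[lo]) / counts
        pieces.append(pd.Series(means[present], index=grid[present]))
    return pd.concat(pieces)


def _plateau_maxima(v: np.ndarray) -> np.ndarray:
    """Indices of local maxima; the leftmost sample of a flat maximal run.

    Run boundaries are never maxima (a strictly smaller neighbor is required
    on both sides).
    """
    if len(v) < 3:
        return np.array([], dtype=int)
    d = np.sign(np.diff(v))
    idx = np.nonzero(d != 0)[0]
    if len(idx) < 2:
        return np.array([], dtype=int)
    s = d[idx]
    tops = np.nonzero((s[:-1] > 0) & (s[1:] < 0))[0]
    return idx[tops] + 1


def _base(v: np.ndarray, p: int, side: int):
    """(min value, argmin index) between peak ``p`` and the nearest strictly
    higher sample on ``side`` (-1 left / +1 right), or the run boundary."""
    x = v[p]
    if side < 0:
        seg = v[:p]
        higher = np.nonzero(seg > x)[0]
        lo = higher[-1] + 1 if higher.size else 0
        arg = lo + int(np.argmin(v[lo:p]))
    else:
        seg = v[p + 1:]
        higher = np.nonzero(seg > x)[0]
        hi = p + 1 + higher[0] if higher.size else len(v)
        arg = p + 1 + int(np.argmin(v[p + 1: hi]))
    return float(v[arg]), arg


def detect_coh_peaks(smoothed: pd.Series, params: CohParams | None = None) -> list:
    """Call COH peaks on a smoothed z series.

    Local maxima (plateaus resolved to their leftmost sample) are kept when
    height >= ``min_peak_height`` and prominence >= ``min_peak_prominence``;
    the minimum-distance constraint is then enforced greedily in descending
    height order (ties in ascending time order), discarding any candidate
    closer than ``min_peak_distance_minutes`` to an already kept peak.
    """
    params = params or CohParams()
    if len(smoothed) == 0:
        return []
    candidates = []
    for run in _run_bounds(smoothed.index, params.max_bridge_gap_minutes):
        chunk = smoothed.iloc[run]
        v = chunk.to_numpy(dtype=float)
        t = chunk.index
        for p in _plateau_maxima(v):
            height = v[p]
            if height < params.min_peak_height:
                continue
            left_val, left_idx = _base(v, p, -1)
            right_val, right_idx = _base(v, p, +1)
            prominence = height - max(left_val, right_val)
            if prominence < params.min_peak_prominence:
                continue
            candidates.append(
                Peak(t[p], float(height), float(prominence), t[left_idx], t[right_idx])
            )
    candidates.sort(key=lambda pk: (-pk.height, pk.time.value))
    min_dist_ns = params.min_peak_distance_minutes * 60_000_000_000
    kept = []
    for pk in candidates:
        if all(abs(pk.time.value - other.time.value) >= min_dist_ns for other in kept):
            kept.append(pk)
    kept.sort(key=lambda pk: pk.time.value)
    return kept


class CohDetector(BaseEstimator):
    """COH detector with a scikit-learn estimator surface.

    ``fit`` accepts a RestingZSeries frame (uses its ``z`` column) or a
    plain z Series on the minute grid, and computes the fitted attributes
    ``smoothed_`` and ``peaks_``.
    """

    def __init__(
        self,
        span_minutes: int = 180,
        min_peak_height: float = 2.0,
        min_peak_distance_minutes: int = 180,
        min_peak_prominence: float = 2.0,
        max_bridge_gap_minutes: int = 180,
    ):
        self.span_minutes = span_minutes
        self.min_peak_height = min_peak_height
        self.min_peak_distance_minutes = min_peak_distance_minutes
        self.min_peak_prominence = min_peak_prominence
        self.max_bridge_gap_minutes = max_bridge_gap_minutes

    def _params(self) -> CohParams:
        return CohParams(
            span_minutes=self.span_minutes,
            min_peak_height=self.min_peak_height,
            min_peak_distance_minutes=self.min_peak_distance_minutes,
            min_peak_prominence=self.min_peak_prominence,
            max_bridge_gap_minutes=self.max_bridge_gap_minutes,
        )

    def fit(self, X, y=None):
        z = X["z"] if isinstance(X, pd.DataFrame) else X
        params = self._params()
        self.smoothed_ = moving_average_smooth(z, params)
        self.peaks_ = detect_coh_peaks(self.smoothed_, params)
        return self

    def fit_detect(self, X) -> list:
        return self.fit(X).peaks_


def peaks_to_frame(peaks) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "time": pk.time.isoformat(),
                "height": pk.height,
                "prominence": pk.prominence,
                "left_base": pk.left_base.isoformat(),
                "right_base": pk.right_base.isoformat(),
            }
            for pk in peaks
        ],
        columns=["time", "height", "prominence", "left_base", "right_base"],
    )
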