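"""Activity-gated resting-state extraction and personalized z-normalization.

The baseline idea: physiological channels (heart rate, skin temperature) are
only comparable across time once activity effects are removed.  A minute is
*resting* when the step counter has read zero for a lookback window (10 min
by default, including the current minute) and the minute lies inside no
labeled exercise interval.  Resting minutes are then standardized against
the participant's own baseline, stratified by sleep/wake state (or by hour
of day when no sleep track exists) and by device, over the whole monitoring
period.  The daily *percentage of outliers* is the fraction of a day's
resting minutes whose z-score exceeds 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._errors import (
    DegenerateBaselineError,
    InsufficientBaselineError,
    ValidationError,
)
from .streams import (
    EXERCISE_LABELS,
    SleepWakeTrack,
    TimeStampedSeries,
    WearableDataset,
    resample_minute,
)


@dataclass
class NormParams:
    """Tunables of the resting-state normalization.

    lookback_minutes
        Zero-step window (including the current minute) required for a
        minute to count as resting.  ``1`` reproduces the cohort-profile
        convention of requiring only the current minute to be step-free.
    outlier_z
        Z threshold for the daily outlier fraction.
    outlier_sided
        ``upper`` counts only z > threshold (elevated values); ``two_sided``
        counts |z| > threshold.
    min_stratum_minutes
        Minimum resting minutes a baseline stratum must contain.
    stratification
        ``sleep_wake`` (default) or ``hour_of_day`` for records without a
        sleep track.
    """

    lookback_minutes: int = 10
    outlier_z: float = 2.0
    outlier_sided: str = "upper"
    min_stratum_minutes: int = 500
    stratification: str = "sleep_wake"

    def __post_init__(self):
        if self.lookback_minutes < 0:
            raise ValidationError("lookback_minutes must be >= 0")
        if self.outlier_z <= 0:
            raise ValidationError("outlier_z must be > 0")
        if self.outlier_sided not in ("upper", "two_sided"):
            raise ValidationError(f"unknown outlier_sided {self.outlier_sided!r}")
        if self.stratification not in ("sleep_wake", "hour_of_day"):
            raise ValidationError(f"unknown stratification {self.stratification!r}")


def resting_mask(
    steps: TimeStampedSeries, activities, params: NormParams | None = None
) -> pd.Series:
    """Boolean mask over the minute grid spanning ``steps``.

    Minute ``m`` is True iff a step sample is present and zero at ``m``,
    every present step minute in ``(m - lookback, m]`` is zero, and ``m``
    lies inside no walking/running/cycling/flight interval.  Minutes with
    absent step data are False (conservative).
    """
    params = params or NormParams()
    s = steps.data
    if len(s) == 0:
        return pd.Series(dtype=bool)
    grid = pd.date_range(s.index[0].floor("min"), s.index[-1].floor("min"), freq="min")
    vals = s.reindex(grid)
    present_zero = (vals == 0).fillna(False).to_numpy(dtype=bool)
    window = max(int(params.lookback_minutes), 1)
    moved = (vals > 0).fillna(False).astype(float)
    recent_any = moved.rolling(window, min_periods=1).max().to_numpy() > 0
    mask = present_zero & ~recent_any
    if activities:
        t = grid.asi8
        for act in activities:
            if act.label in EXERCISE_LABELS:
                mask[(t >= act.start.value) & (t < act.end.value)] = False
    return pd.Series(mask, index=grid, name="resting")


def _strata_labels(index: pd.DatetimeIndex, sleep: SleepWakeTrack | None, params: NormParams):
    if params.stratification == "hour_of_day":
        return index.hour.astype(str)
    if sleep is None:
        raise ValidationError(
            "sleep_wake stratification requires a sleep track; use hour_of_day instead"
        )
    return sleep.state_at(index)


def stratified_zscore(
    series: TimeStampedSeries,
    sleep: SleepWakeTrack | None,
    mask: pd.Series,
    params: NormParams | None = None,
    baseline: dict | None = None,
) -> pd.DataFrame:
    """Standardize masked resting minutes against per-stratum baselines.

    Returns a frame indexed by timestamp with columns ``raw``, ``z``,
    ``stratum`` and ``device_id`` (the RestingZSeries).  Baselines are the
    mean and sample (n-1) SD of all masked minutes sharing the stratum over
    the whole record; pass ``baseline`` (as returned by
    :func:`baseline_statistics`) to reuse precomputed cells.
    """
    params = params or NormParams()
    x = series.data
    keep = mask.reindex(x.index, fill_value=False).to_numpy(dtype=bool)
    x = x[keep]
    strata = np.asarray(_strata_labels(x.index, sleep, params))
    if baseline is None:
        baseline = _fit_baseline(x.to_numpy(), strata, series.device_id, params)
    z = np.empty(len(x))
    for stratum in np.unique(strata):
        cell = (stratum, series.device_id)
        if cell not in baseline:
            raise InsufficientBaselineError(f"no baseline for stratum cell {cell}")
        mean, sd, _ = baseline[cell]
        sel = strata == stratum
        z[sel] = (x.to_numpy()[sel] - mean) / sd
    return pd.DataFrame(
        {
            "raw": x.to_numpy(),
            "z": z,
            "stratum": strata,
            "device_id": series.device_id,
        },
        index=x.index,
    )


def _fit_baseline(values: np.ndarray, strata: np.ndarray, device_id: str, params: NormParams) -> dict:
    baseline = {}
    for stratum in np.unique(strata):
        sel = values[strata == stratum]
        if len(sel) < params.min_stratum_minutes:
            raise InsufficientBaselineError(
                f"stratum cell ({stratum!r}, {device_id!r}) has {len(sel)} resting minutes "
                f"(< {params.min_stratum_minutes})"
            )
        sd = float(np.std(sel, ddof=1))
        if sd == 0:
            raise DegenerateBaselineError(
                f"stratum cell ({stratum!r}, {device_id!r}) has zero variance"
            )
        baseline[(stratum, device_id)] = (float(np.mean(sel)), sd, len(sel))
    return baseline


def daily_outlier_fraction(
    z: pd.DataFrame, params: NormParams | None = None, channel: str = ""
) -> pd.DataFrame:
    """Per-UTC-day fraction of resting minutes whose z exceeds the threshold.

    Days with zero resting minutes are simply absent.
    """
    params = params or NormParams()
    if z.empty:
        raise ValidationError("empty resting z series")
    if params.outlier_sided == "upper":
        hit = z["z"].to_numpy() > params.outlier_z
    else:
        hit = np.abs(z["z"].to_numpy()) > params.outlier_z
    frame = pd.DataFrame({"hit": hit}, index=z.index)
    grouped = frame.groupby(frame.index.tz_convert("UTC").date)["hit"].agg(["size", "mean"])
    return pd.DataFrame(
        {
            "date": grouped.index,
            "channel": channel,
            "n_resting_minutes": grouped["size"].to_numpy(),
            "fraction_outliers": grouped["mean"].to_numpy(),
        }
    ).reset_index(drop=True)


class RestingZScorer(BaseEstimator, TransformerMixin):
    """Personalized resting-state z-scorer, scikit-learn style.

    ``fit`` takes a :class:`~cohwear.streams.WearableDataset`, resamples the
    chosen channel to the minute grid, derives the resting mask from the
    step stream and learns per-(stratum, device) baseline statistics.
    ``transform`` returns the RestingZSeries frame.  Fitted attributes carry
    a trailing underscore.
    """

    def __init__(
        self,
        channel: str = "heart_rate_bpm",
        lookback_minutes: int = 10,
        outlier_z: float = 2.0,
        outlier_sided: str = "upper",
        min_stratum_minutes: int = 500,
        stratification: str = "sleep_wake",
    ):
        self.channel = channel
        self.lookback_minutes = lookback_minutes
        self.outlier_z = outlier_z
        self.outlier_sided = outlier_sided
        self.min_stratum_minutes = min_stratum_minutes
        self.stratification = stratification

    def _params(self) -> NormParams:
        return NormParams(
            lookback_minutes=self.lookback_minutes,
            outlier_z=self.outlier_z,
            outlier_sided=self.outlier_sided,
            min_stratum_minutes=self.min_stratum_minutes,
            stratification=self.stratification,
        )

    def fit(self, X: WearableDataset, y=None):
        params = self._params()
        steps = X.get_streams("steps_per_min")
        if not steps:
            raise ValidationError("dataset has no step stream; cannot build a resting mask")
        self.mask_ = resting_mask(resample_minute(steps[0]), X.activities, params)
        frames = []
        self.baseline_ = {}
        for stream in X.get_streams(self.channel):
            minute = resample_minute(stream)
            zf = stratified_zscore(minute, X.sleep, self.mask_, params)
            for stratum in np.unique(zf["stratum"]):
                cell_vals = zf.loc[zf["stratum"] == stratum, "raw"].to_numpy()
                self.baseline_[(str(stratum), stream.device_id)] = (
                    float(np.mean(cell_vals)),
                    float(np.std(cell_vals, ddof=1)),
                    len(cell_vals),
                )
            frames.append(zf)
        if not frames:
            raise ValidationError(f"dataset has no {self.channel!r} stream")
        self.z_ = pd.concat(frames).sort_index()
        return self

    def transform(self, X=None) -> pd.DataFrame:
        """Return the RestingZSeries of the fitted record.

        ``X`` is accepted for scikit-learn pipeline compatibility; the
        baselines and z-scores always refer to the record seen by ``fit``.
        """
        if not hasattr(self, "z_"):
            raise ValidationError("RestingZScorer is not fitted")
        return self.z_

    def daily_outliers(self) -> pd.DataFrame:
        if not hasattr(self, "z_"):
            raise ValidationError("RestingZScorer is not fitted")
        return daily_outlier_fraction(self.z_, self._params(), channel=self.channel)


def write_resting_z_csv(z: pd.DataFrame, path) -> None:
    out = z.copy()
    out.insert(0, "timestamp", [t.isoformat() for t in z.index])
    out.to_csv(path, index=False)


def write_daily_outliers_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)
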