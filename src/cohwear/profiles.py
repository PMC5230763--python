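"""Diurnal profiles, device agreement and exposure summaries.

Hour-of-day operations use the dataset's home timezone with a
daylight-saving-aware clock.  The day/night capture windows follow the
cohort convention: one daytime hour (3-4 p.m. local) qualifying only when
more than 30 steps were taken in the hour, and one nighttime hour
(3-4 a.m.) qualifying only when fewer than 5 steps were recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import NotComputableError, UndefinedStatisticError, ValidationError
from .streams import TimeStampedSeries


@dataclass
class AgreementResult:
    """Bland-Altman agreement between two devices (differences a - b)."""

    mean_difference: float
    lower_loa: float
    upper_loa: float
    pearson_r: float | None  # None-flagged when undefined (constant input)
    n_pairs: int


@dataclass
class DayNightDelta:
    day_mean: float
    night_mean: float
    delta: float
    n_day_hours: int
    n_night_hours: int


def hourly_summaries(
    series: TimeStampedSeries, dates=None, tz: str = "UTC"
) -> pd.DataFrame:
    """Mean per (local date, local hour) cell; empty cells absent.

    ``dates`` optionally restricts to a set of included local calendar days
    (e.g. after travel-day exclusion).  Returns a long frame with columns
    ``date, hour, mean, n``.
    """
    local = series.data.tz_convert(tz)
    frame = pd.DataFrame(
        {"value": local.to_numpy(), "date": local.index.date, "hour": local.index.hour}
    )
    if dates is not None:
        frame = frame[frame["date"].isin(set(dates))]
    grouped = frame.groupby(["date", "hour"])["value"].agg(["mean", "size"])
    out = grouped.reset_index().rename(columns={"size": "n"})
    return out[["date", "hour", "mean", "n"]]


def day_night_delta(
    series: TimeStampedSeries,
    steps: TimeStampedSeries,
    tz: str = "UTC",
    day_hour: int = 15,
    night_hour: int = 3,
    day_min_steps: float = 30.0,
    night_max_steps: float = 5.0,
) -> DayNightDelta:
    """Day-minus-night mean over the qualifying capture hours.

    A day hour qualifies with strictly more than ``day_min_steps`` recorded
    steps; a night hour with strictly fewer than ``night_max_steps`` (and at
    least one step sample, so silence is not mistaken for stillness).
    """
    local = series.data.tz_convert(tz)
    local_steps = steps.data.tz_convert(tz)

    def _qualifying_dates(hour, predicate):
        sel = local_steps[local_steps.index.hour == hour]
        sums = sel.groupby(sel.index.date).sum()
        return {d for d, total in sums.items() if predicate(total)}

    day_dates = _qualifying_dates(day_hour, lambda s: s > day_min_steps)
    night_dates = _qualifying_dates(night_hour, lambda s: s < night_max_steps)
    day_vals = local[(local.index.hour == day_hour) & pd.Index(local.index.date).isin(day_dates)]
    night_vals = local[
        (local.index.hour == night_hour) & pd.Index(local.index.date).isin(night_dates)
    ]
    if len(day_vals) == 0:
        raise NotComputableError("no qualifying day (3-4 p.m., >30 steps) hours")
    if len(night_vals) == 0:
        raise NotComputableError("no qualifying night (3-4 a.m., <5 steps) hours")
    day_mean = float(day_vals.mean())
    night_mean = float(night_vals.mean())
    return DayNightDelta(
        day_mean, night_mean, day_mean - night_mean, len(day_dates), len(night_dates)
    )


def average_steps_per_day(steps: TimeStampedSeries) -> float:
    """Average step rate per second scaled to a day (86,400 s)."""
    if len(steps) == 0:
        raise ValidationError("empty step series")
    per_second = float(steps.data.mean()) / 60.0
    return per_second * 86_400.0


def bland_altman_agreement(a: TimeStampedSeries, b: TimeStampedSeries) -> AgreementResult:
    """Agreement of two devices: mean difference, 95% limits, Pearson r.

    Pairs are formed by matching timestamps exactly; limits are
    mean +/- 1.96 x sample SD of the differences.
    """
    joined = pd.concat([a.data.rename("a"), b.data.rename("b")], axis=1, join="inner")
    if len(joined) < 3:
        raise ValidationError(f"need >= 3 matched pairs, got {len(joined)}")
    d = joined["a"].to_numpy() - joined["b"].to_numpy()
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    if np.ptp(joined["a"].to_numpy()) == 0 or np.ptp(joined["b"].to_numpy()) == 0:
        r = None
    else:
        r = float(stats.pearsonr(joined["a"], joined["b"])[0])
    return AgreementResult(
        mean_difference=mean_d,
        lower_loa=mean_d - 1.96 * sd_d,
        upper_loa=mean_d + 1.96 * sd_d,
        pearson_r=r,
        n_pairs=len(joined),
    )


def exposure_fold_increase(rates, baseline_rate: float) -> float:
    """Typical elevated radiation rate over background, to one decimal place.

    ``rates`` may be a scalar typical rate or a collection of
    elevated-window samples (their mean is used).
    """
    if baseline_rate <= 0:
        raise ValidationError("baseline rate must be positive")
    if isinstance(rates, TimeStampedSeries):
        elevated = float(rates.data.mean())
    elif np.isscalar(rates):
        elevated = float(rates)
    else:
        elevated = float(np.mean(np.asarray(rates, dtype=float)))
    return round(elevated / baseline_rate, 1)
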