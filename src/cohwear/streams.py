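"""Core data model for wearable sensor streams.

A participant's record is a collection of per-channel, per-device
:class:`TimeStampedSeries` on a UTC time axis, plus a sleep/wake interval
track and labeled activity intervals.  Days are defined by the UTC calendar
(half-open ``[00:00, 24:00)``) so that travel across time zones does not
split or duplicate days.  Gaps in a stream are represented by absent rows,
never by sentinel values.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ValidationError

CHANNELS = (
    "heart_rate_bpm",
    "skin_temp_f",
    "spo2_pct",
    "steps_per_min",
    "radiation_mrem_per_h",
)

ACTIVITY_LABELS = ("walking", "running", "cycling", "flight", "other")

#: Labels that disqualify a minute from being "resting".
EXERCISE_LABELS = frozenset({"walking", "running", "cycling", "flight"})

# (low, high, low_inclusive, high_inclusive) physiologic bounds per channel
_CHANNEL_BOUNDS = {
    "heart_rate_bpm": (0.0, 300.0, False, False),
    "spo2_pct": (0.0, 100.0, True, True),
    "steps_per_min": (0.0, np.inf, True, True),
    "radiation_mrem_per_h": (0.0, np.inf, True, True),
}


def value_in_bounds(channel: str, values: np.ndarray) -> np.ndarray:
    """Boolean mask of values satisfying the channel's physiologic bounds."""
    if channel not in _CHANNEL_BOUNDS:
        return np.ones(len(values), dtype=bool)
    lo, hi, lo_inc, hi_inc = _CHANNEL_BOUNDS[channel]
    ok_lo = values >= lo if lo_inc else values > lo
    ok_hi = values <= hi if hi_inc else values < hi
    return ok_lo & ok_hi


def _as_utc_index(index) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(index)
    if idx.tz is None:
        raise ValidationError("timestamps must be timezone-aware")
    return idx.tz_convert("UTC")


@dataclass(eq=False)
class TimeStampedSeries:
    """One sensor channel for one participant/device.

    ``data`` is a float Series indexed by a strictly increasing UTC
    DatetimeIndex with no NaN values (gaps are absent rows).
    """

    participant_id: str
    device_id: str
    channel: str
    data: pd.Series

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValidationError(f"unknown channel {self.channel!r}")
        idx = _as_utc_index(self.data.index)
        values = np.asarray(self.data.to_numpy(), dtype=float)
        if np.isnan(values).any():
            raise ValidationError(f"{self.channel}: NaN values are not allowed; drop the rows")
        if len(idx) > 1:
            deltas = np.diff(idx.asi8)
            if (deltas == 0).any():
                pos = int(np.nonzero(deltas == 0)[0][0]) + 1
                raise ValidationError(
                    f"{self.channel}/{self.device_id}: duplicate timestamp at row {pos} ({idx[pos]})"
                )
            if (deltas < 0).any():
                pos = int(np.nonzero(deltas < 0)[0][0]) + 1
                raise ValidationError(
                    f"{self.channel}/{self.device_id}: non-monotone timestamp at row {pos} ({idx[pos]})"
                )
        bad = ~value_in_bounds(self.channel, values)
        if bad.any():
            pos = int(np.nonzero(bad)[0][0])
            raise ValidationError(
                f"{self.channel}: value {values[pos]} out of range at {idx[pos]}"
            )
        self.data = pd.Series(values, index=idx, name=self.channel)

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TimeStampedSeries):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.device_id == other.device_id
            and self.channel == other.channel
            and self.data.index.equals(other.data.index)
            and np.allclose(self.data.to_numpy(), other.data.to_numpy(), atol=1e-9)
        )

    def with_data(self, data: pd.Series) -> "TimeStampedSeries":
        return TimeStampedSeries(self.participant_id, self.device_id, self.channel, data)


@dataclass
class SleepWakeTrack:
    """Non-overlapping ``(start, end, state)`` intervals; state is sleep/wake.

    Instants not covered by any interval are treated as wake.
    """

    intervals: list  # of (Timestamp, Timestamp, str)

    def __post_init__(self):
        ivs = []
        for start, end, state in self.intervals:
            start, end = pd.Timestamp(start), pd.Timestamp(end)
            if start.tz is None or end.tz is None:
                raise ValidationError("sleep intervals must be timezone-aware")
            start, end = start.tz_convert("UTC"), end.tz_convert("UTC")
            if state not in ("sleep", "wake"):
                raise ValidationError(f"unknown sleep state {state!r}")
            if not start < end:
                raise ValidationError(f"sleep interval start {start} not before end {end}")
            ivs.append((start, end, state))
        ivs.sort(key=lambda t: t[0])
        for (s0, e0, _), (s1, _, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValidationError(f"overlapping sleep intervals at {s1}")
        self.intervals = ivs

    def state_at(self, index) -> np.ndarray:
        """Array of 'sleep'/'wake' for each instant (uncovered -> wake)."""
        idx = _as_utc_index(index)
        out = np.full(len(idx), "wake", dtype=object)
        sleeps = [(s, e) for s, e, st in self.intervals if st == "sleep"]
        if sleeps:
            starts = np.array([s.value for s, _ in sleeps])
            ends = np.array([e.value for _, e in sleeps])
            pos = np.searchsorted(starts, idx.asi8, side="right") - 1
            inside = (pos >= 0) & (idx.asi8 < ends[np.clip(pos, 0, None)])
            out[inside] = "sleep"
        return out


@dataclass(frozen=True)
class ActivityInterval:
    """A labeled activity span; half-open ``[start, end)``."""

    start: pd.Timestamp
    end: pd.Timestamp
    label: str
    source: str = "log"

    def __post_init__(self):
        start = pd.Timestamp(self.start)
        end = pd.Timestamp(self.end)
        if start.tz is None or end.tz is None:
            raise ValidationError("activity intervals must be timezone-aware")
        object.__setattr__(self, "start", start.tz_convert("UTC"))
        object.__setattr__(self, "end", end.tz_convert("UTC"))
        if self.label not in ACTIVITY_LABELS:
            raise ValidationError(f"unknown activity label {self.label!r}")
        if self.source not in ("device", "app", "log"):
            raise ValidationError(f"unknown activity source {self.source!r}")
        if not self.start < self.end:
            raise ValidationError("activity interval start must precede end")


@dataclass
class WearableDataset:
    """All streams, the sleep track and activity labels for one participant."""

    streams: list  # of TimeStampedSeries
    sleep: SleepWakeTrack | None = None
    activities: list = field(default_factory=list)
    home_timezone: str = "UTC"

    def __post_init__(self):
        pids = {s.participant_id for s in self.streams}
        if len(pids) > 1:
            raise ValidationError(f"streams span multiple participants: {sorted(pids)}")

    @property
    def participant_id(self) -> str:
        return self.streams[0].participant_id if self.streams else ""

    def get_streams(self, channel: str, device_id: str | None = None) -> list:
        out = [s for s in self.streams if s.channel == channel]
        if device_id is not None:
            out = [s for s in out if s.device_id == device_id]
        return out

    def get_stream(self, channel: str, device_id: str | None = None) -> TimeStampedSeries:
        matches = self.get_streams(channel, device_id)
        if not matches:
            raise KeyError(f"no stream for channel {channel!r}")
        if len(matches) > 1:
            raise KeyError(f"multiple streams for channel {channel!r}; pass device_id")
        return matches[0]


# ---------------------------------------------------------------------------
# calendar operations


def resample_minute(series: TimeStampedSeries) -> TimeStampedSeries:
    """Collapse a stream to one sample per calendar minute (median of in-minute samples).

    Minutes containing no input sample are absent from the output.
    """
    if len(series) == 0:
        raise ValidationError("cannot resample an empty series")
    med = series.data.groupby(series.data.index.floor("min")).median()
    return series.with_data(med)


def partition_days_utc(series: TimeStampedSeries) -> dict:
    """Split a stream by UTC calendar day (half-open [00:00, 24:00))."""
    out = {}
    if len(series) == 0:
        return out
    for day, chunk in series.data.groupby(series.data.index.tz_convert("UTC").date):
        out[day] = series.with_data(chunk)
    return out


def exclude_travel_days(dates, travel_days) -> set:
    """Drop every travel day and the 2 calendar days following each travel day."""
    excluded = set()
    for day in travel_days:
        for k in range(3):
            excluded.add(day + _dt.timedelta(days=k))
    return set(dates) - excluded
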