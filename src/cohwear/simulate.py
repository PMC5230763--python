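"""Synthetic wearable datasets with ground truth.

The generator emulates the statistical structure the analysis assumes:
minute-resolution heart rate and skin temperature with sleep/wake strata
(HR 69.2 +/- 7.7 BPM asleep, 84.5 +/- 11.3 BPM awake; skin temperature
91.3 +/- 2.0 F asleep, 86.6 +/- 3.2 F awake), AR(1) minute-level noise
(autocorrelation 0.8) so that smoothing and peak calling are non-trivial,
activity bouts that elevate HR toward the activity means (walking 101.1,
cycling 114.1, running 145.2 BPM) and produce non-zero steps, brief
incidental "other" movement each waking hour, random minute deletion for
missingness, illness events that raise resting-minute values by a stated
number of stratum SDs, CRP that tracks illness with exponential decay and
log-normal measurement noise, and flights with altitude-coupled SpO2,
late-flight adaptation and fatigue-coupled psychomotor vigilance tests.

Everything is reproducible from ``(params, seed)``.
"""

from __future__ import annotations


import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from ._errors import ValidationError
from .normalize import NormParams, resting_mask
from .streams import (
    ActivityInterval,
    SleepWakeTrack,
    TimeStampedSeries,
    WearableDataset,
    resample_minute,
)
from .flight import FlightRecord, PvtSession

_START = pd.Timestamp("2017-01-01 00:00", tz="UTC")

#: per-archetype exercise bouts as (start_hour, duration_minutes, label)
_SCHEDULES = {
    "morning": [(7.0, 45, "running")],
    "commuter": [(8.0, 30, "walking"), (17.5, 30, "walking")],
    "all_day": [(9.0, 15, "walking"), (11.0, 15, "walking"), (13.0, 15, "walking"),
                (17.0, 15, "cycling")],
    "mealtimes": [(8.0, 20, "walking"), (12.5, 20, "walking"), (18.5, 20, "walking")],
}

_STEP_RATES = {"walking": 105.0, "running": 165.0, "cycling": 8.0, "other": 22.0}


@dataclass
class SimParams:
    """Study conditions of the simulator (units in field names/docstring)."""

    n_days: int = 100
    seed: int = 0
    hr_sleep_mean: float = 69.2
    hr_sleep_sd: float = 7.7
    hr_wake_mean: float = 84.5
    hr_wake_sd: float = 11.3
    temp_sleep_mean: float = 91.3
    temp_sleep_sd: float = 2.0
    temp_wake_mean: float = 86.6
    temp_wake_sd: float = 3.2
    activity_hr_means: dict = field(
        default_factory=lambda: {"walking": 101.1, "cycling": 114.1, "running": 145.2}
    )
    activity_hr_sd: float = 15.0
    #: small additive HR elevation during incidental ("other") movement
    other_hr_boost: float = 3.0
    sleep_start_hour: int = 22
    sleep_end_hour: int = 6
    activity_schedule: str = "commuter"
    missingness: float = 0.05
    ar1_phi: float = 0.8
    participant_id: str = "sim-001"
    device_id: str = "basis-peak"
    home_timezone: str = "UTC"

    def __post_init__(self):
        for name in ("hr_sleep_sd", "hr_wake_sd", "temp_sleep_sd", "temp_wake_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0 <= self.missingness < 1:
            raise ValidationError("missingness must be in [0, 1)")
        if self.activity_schedule not in _SCHEDULES:
            raise ValidationError(f"unknown activity schedule {self.activity_schedule!r}")


@dataclass(frozen=True)
class IllnessEvent:
    """Ground-truth illness: additive shift in stratum-SD units on resting minutes."""

    onset: pd.Timestamp
    duration_hours: float
    hr_effect_sd: float
    temp_effect_sd: float = 0.0
    crp_peak: float = 10.0

    def __post_init__(self):
        if self.duration_hours <= 0:
            raise ValidationError("event duration must be > 0")
        if self.hr_effect_sd < 0 or self.temp_effect_sd < 0:
            raise ValidationError("effects must be >= 0")

    @property
    def end(self) -> pd.Timestamp:
        return self.onset + pd.Timedelta(hours=self.duration_hours)


@dataclass
class SyntheticTruth:
    """Generator parameters plus the injected event tables."""

    params: SimParams
    seed: int
    illness_events: list = field(default_factory=list)
    flights: list = field(default_factory=list)


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Unit-marginal-variance AR(1) path."""
    e = rng.standard_normal(n)
    if n > 1:
        e[1:] *= np.sqrt(1.0 - phi * phi)
    return lfilter([1.0], [1.0, -phi], e)


def simulate_participant(params: SimParams | None = None):
    """Generate one participant's record; returns ``(dataset, truth)``."""
    params = params or SimParams()
    rng = np.random.default_rng(params.seed)
    n = params.n_days * 1440
    idx = pd.date_range(_START, periods=n, freq="min")
    hour = idx.hour.to_numpy()
    if params.sleep_start_hour > params.sleep_end_hour:
        asleep = (hour >= params.sleep_start_hour) | (hour < params.sleep_end_hour)
    else:
        asleep = (hour >= params.sleep_start_hour) & (hour < params.sleep_end_hour)

    hr_noise = _ar1(rng, n, params.ar1_phi)
    temp_noise = _ar1(rng, n, params.ar1_phi)
    hr = np.where(
        asleep,
        params.hr_sleep_mean + params.hr_sleep_sd * hr_noise,
        params.hr_wake_mean + params.hr_wake_sd * hr_noise,
    )
    temp = np.where(
        asleep,
        params.temp_sleep_mean + params.temp_sleep_sd * temp_noise,
        params.temp_wake_mean + params.temp_wake_sd * temp_noise,
    )
    steps = np.zeros(n)

    activities = []
    day_starts = np.arange(params.n_days) * 1440
    # scheduled exercise bouts, with a little day-to-day start jitter
    for start_hour, dur, label in _SCHEDULES[params.activity_schedule]:
        jitter = rng.integers(-10, 11, size=params.n_days)
        starts = day_starts + int(start_hour * 60) + jitter
        for s in starts:
            e = min(s + dur, n)
            if s < 0 or s >= n:
                continue
            sl = slice(int(s), int(e))
            m = e - s
            steps[sl] = np.maximum(
                rng.normal(_STEP_RATES[label], 0.15 * _STEP_RATES[label], m), 1.0
            )
            hr[sl] = params.activity_hr_means[label] + params.activity_hr_sd * hr_noise[sl]
            activities.append(
                ActivityInterval(idx[sl.start], idx[sl.start] + pd.Timedelta(minutes=m), label, "app")
            )
    # incidental movement: a 2-min stroll at the top of each waking hour
    for h in range(9, 21):
        starts = day_starts + h * 60
        for s in starts:
            sl = slice(int(s), int(min(s + 2, n)))
            if sl.stop <= sl.start or steps[sl].max() > 0:
                continue  # do not overwrite an exercise bout
            steps[sl] = np.maximum(rng.normal(_STEP_RATES["other"], 4.0, sl.stop - sl.start), 1.0)
            hr[sl] = hr[sl] + params.other_hr_boost

    keep = rng.random(n) >= params.missingness
    pid, dev = params.participant_id, params.device_id
    streams = [
        TimeStampedSeries(pid, dev, "heart_rate_bpm", pd.Series(np.clip(hr[keep], 30, 250), index=idx[keep])),
        TimeStampedSeries(pid, dev, "skin_temp_f", pd.Series(temp[keep], index=idx[keep])),
        TimeStampedSeries(pid, dev, "steps_per_min", pd.Series(steps[keep], index=idx[keep])),
    ]
    sleep_track = _mask_to_track(asleep, idx)
    dataset = WearableDataset(
        streams, sleep=sleep_track, activities=activities, home_timezone=params.home_timezone
    )
    truth = SyntheticTruth(params=params, seed=params.seed)
    return dataset, truth


def _mask_to_track(asleep: np.ndarray, idx: pd.DatetimeIndex) -> SleepWakeTrack:
    edges = np.nonzero(np.diff(asleep.astype(np.int8)))[0] + 1
    bounds = np.concatenate([[0], edges, [len(asleep)]])
    intervals = []
    minute = pd.Timedelta(minutes=1)
    for a, b in zip(bounds[:-1], bounds[1:]):
        state = "sleep" if asleep[a] else "wake"
        intervals.append((idx[a], idx[b - 1] + minute, state))
    return SleepWakeTrack(intervals)


def inject_illness(dataset: WearableDataset, truth: SyntheticTruth, events):
    """Raise resting-minute HR/temperature during each event; returns
    ``(dataset', truth')`` with the truth table extended.

    Effects are additive in units of the generator's stratum SDs, so
    recovery through the normalization stage is exact by construction.
    Overlapping events are rejected to keep the truth unambiguous.
    """
    events = sorted(events, key=lambda ev: ev.onset)
    for a, b in zip(events, events[1:]):
        if b.onset < a.end:
            raise ValidationError("overlapping illness events")
    steps = dataset.get_stream("steps_per_min")
    span = (steps.data.index[0], steps.data.index[-1])
    for ev in events:
        if ev.onset < span[0] or ev.end > span[1] + pd.Timedelta(minutes=1):
            raise ValidationError(f"event at {ev.onset} outside the dataset span")
    mask = resting_mask(resample_minute(steps), dataset.activities, NormParams())
    params = truth.params
    new_streams = []
    for stream in dataset.streams:
        if stream.channel == "heart_rate_bpm":
            sds, attr = (params.hr_sleep_sd, params.hr_wake_sd), "hr_effect_sd"
        elif stream.channel == "skin_temp_f":
            sds, attr = (params.temp_sleep_sd, params.temp_wake_sd), "temp_effect_sd"
        else:
            new_streams.append(stream)
            continue
        values = stream.data.to_numpy().copy()
        t = stream.data.index
        resting = mask.reindex(t.floor("min"), fill_value=False).to_numpy(dtype=bool)
        is_sleep = dataset.sleep.state_at(t) == "sleep" if dataset.sleep else np.zeros(len(t), bool)
        sd_per_min = np.where(is_sleep, sds[0], sds[1])
        for ev in events:
            effect = getattr(ev, attr)
            in_event = (t >= ev.onset) & (t < ev.end) & resting
            values[in_event] += effect * sd_per_min[in_event]
        new_streams.append(stream.with_data(pd.Series(values, index=t)))
    new_truth = SyntheticTruth(
        params=params,
        seed=truth.seed,
        illness_events=list(truth.illness_events) + events,
        flights=list(truth.flights),
    )
    return (
        WearableDataset(
            new_streams,
            sleep=dataset.sleep,
            activities=list(dataset.activities),
            home_timezone=dataset.home_timezone,
        ),
        new_truth,
    )


def simulate_crp(
    truth: SyntheticTruth,
    sampling_dates,
    baseline: float = 0.2,
    rise_hours: float = 24.0,
    decay_days: float = 2.0,
    cv: float = 0.1,
    seed: int | None = None,
):
    """CRP measurements (mg/L) on the given dates.

    Baseline 0.2 mg/L off-events; linear rise to the event's peak over
    ``rise_hours``; exponential decay with time constant ``decay_days``
    after resolution; multiplicative log-normal noise of the stated CV.
    Returns a frame with columns ``date, value``.
    """
    rng = np.random.default_rng(truth.seed + 101 if seed is None else seed)
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    rows = []
    for d in sampling_dates:
        t = pd.Timestamp(d.isoformat() + " 12:00", tz="UTC") if isinstance(d, _dt.date) else pd.Timestamp(d)
        level = baseline
        for ev in truth.illness_events:
            if ev.onset <= t <= ev.end:
                frac = min(1.0, (t - ev.onset).total_seconds() / 3600.0 / rise_hours)
                level = max(level, baseline + (ev.crp_peak - baseline) * frac)
            elif t > ev.end:
                age_days = (t - ev.end).total_seconds() / 86400.0
                level = max(level, baseline + (ev.crp_peak - baseline) * np.exp(-age_days / decay_days))
        rows.append((d, level * float(np.exp(rng.normal(0.0, sigma)))))
    return pd.DataFrame(rows, columns=["date", "value"])


def simulate_flight_spo2(
    duration_h: float,
    cruise_altitude_ft: float = 36000.0,
    adaptation_onset_h: float = 7.0,
    adaptation_gain_pct: float = 1.5,
    ground_spo2_pct: float = 98.0,
    cruise_drop_pct: float = 5.0,
    noise_sd_pct: float = 0.8,
    pvt_interval_min: int = 20,
    seed: int = 0,
):
    """One flight: SpO2 stream, flight record with altitude trace, PVT sessions.

    Altitude is trapezoidal; true SpO2 is the ground baseline minus a drop
    proportional to altitude (``cruise_drop_pct`` at cruise), plus a linear
    adaptation ramp of ``adaptation_gain_pct`` from ``adaptation_onset_h``
    to landing, plus Gaussian noise.  PVT mean response time rises linearly
    with the instantaneous SpO2 deficit, and tired/alert labels threshold a
    latent fatigue equal to the deficit plus noise.
    """
    if duration_h <= 0:
        raise ValidationError("flight duration must be > 0")
    rng = np.random.default_rng(seed)
    takeoff = pd.Timestamp("2017-03-01 12:00", tz="UTC")
    landing = takeoff + pd.Timedelta(hours=duration_h)
    dur_min = duration_h * 60.0
    climb = min(25.0, dur_min / 4.0)

    def altitude_at(mins_since_takeoff: np.ndarray) -> np.ndarray:
        m = np.asarray(mins_since_takeoff, dtype=float)
        up = np.clip(m / climb, 0.0, 1.0)
        down = np.clip((dur_min - m) / climb, 0.0, 1.0)
        alt = cruise_altitude_ft * np.minimum(up, down)
        alt[(m < 0) | (m > dur_min)] = 0.0
        return alt

    trace_times = pd.date_range(
        takeoff - pd.Timedelta(minutes=10), landing + pd.Timedelta(minutes=10), freq="2min"
    )
    trace_min = (trace_times - takeoff).total_seconds() / 60.0
    trace = pd.Series(altitude_at(trace_min), index=trace_times)

    spo2_times = pd.date_range(
        takeoff - pd.Timedelta(minutes=30), landing + pd.Timedelta(minutes=30), freq="min"
    )
    mins = (spo2_times - takeoff).total_seconds() / 60.0
    alt = altitude_at(mins)
    hours = mins / 60.0
    airborne = (mins >= 0) & (mins <= dur_min)
    if duration_h > adaptation_onset_h:
        ramp = np.clip(
            (hours - adaptation_onset_h) / (duration_h - adaptation_onset_h), 0.0, 1.0
        )
    else:
        ramp = np.zeros(len(hours))
    true_spo2 = (
        ground_spo2_pct
        - cruise_drop_pct * alt / cruise_altitude_ft
        + adaptation_gain_pct * ramp * airborne
    )
    observed = np.clip(true_spo2 + rng.normal(0.0, noise_sd_pct, len(spo2_times)), 70.0, 100.0)
    spo2 = TimeStampedSeries(
        "sim-001", "masimo", "spo2_pct", pd.Series(observed, index=spo2_times)
    )
    flight = FlightRecord("sim-flight-001", takeoff, landing, trace)

    sessions = []
    t = takeoff
    while t <= landing:
        m = (t - takeoff).total_seconds() / 60.0
        deficit = ground_spo2_pct - float(
            ground_spo2_pct
            - cruise_drop_pct * altitude_at(np.array([m]))[0] / cruise_altitude_ft
            + (adaptation_gain_pct * np.clip((m / 60.0 - adaptation_onset_h)
                                             / max(duration_h - adaptation_onset_h, 1e-9), 0, 1)
               if duration_h > adaptation_onset_h else 0.0)
        )
        rts = np.clip(rng.normal(230.0 + 12.0 * deficit, 40.0, 12), 150.0, None)
        rt_list = [None if rng.random() < 0.02 else float(r) for r in rts]
        fatigue = deficit + rng.normal(0.0, 0.7)
        label = "tired" if fatigue > 3.5 else ("alert" if fatigue < 1.5 else "in_between")
        sessions.append(PvtSession(t, rt_list, label))
        t = t + pd.Timedelta(minutes=pvt_interval_min)
    return spo2, flight, sessions


def fatigue_samples(spo2: TimeStampedSeries, sessions) -> pd.DataFrame:
    """Join each PVT session's alertness label to the nearest SpO2 sample."""
    left = pd.DataFrame(
        {"t": [s.timestamp for s in sessions], "alertness": [s.alertness_label for s in sessions]}
    )
    right = pd.DataFrame({"t": spo2.data.index, "spo2_pct": spo2.data.to_numpy()})
    joined = pd.merge_asof(
        left.sort_values("t"), right, on="t", direction="nearest",
        tolerance=pd.Timedelta(minutes=5),
    )
    return joined.dropna(subset=["spo2_pct"])[["spo2_pct", "alertness"]]


def write_truth_csv(truth: SyntheticTruth, path) -> None:
    rows = [
        {
            "kind": "illness",
            "onset": ev.onset.isoformat(),
            "duration_h": ev.duration_hours,
            "effect_sd": ev.hr_effect_sd,
            "crp_peak": ev.crp_peak,
        }
        for ev in truth.illness_events
    ]
    pd.DataFrame(rows, columns=["kind", "onset", "duration_h", "effect_sd", "crp_peak"]).to_csv(
        path, index=False
    )
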