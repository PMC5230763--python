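"""Flight-stage SpO2 analyses.

Each flight is partitioned into five stages — pre-takeoff, ascent, cruise,
descent, post-landing — where cruise is defined as the period at or above
95% of the maximum recorded altitude.  SpO2 samples are joined to the
(sparse) altitude trace by nearest timestamp within a 5-minute tolerance.
On top of the stage labels the module provides category-fraction summaries
(>=97%, 91-96%, <91%), Pearson correlation of SpO2 with altitude, the
late-flight adaptation tests (last-quarter rank-sum comparison and the
>7 h vs <2 h Kolmogorov-Smirnov comparison at high altitude), the
tired-vs-alert SpO2 comparison, and psychomotor-vigilance-test summaries
with 500 ms censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import UndefinedStatisticError, ValidationError
from .streams import TimeStampedSeries

STAGES = ("pre_takeoff", "ascent", "cruise", "descent", "post_landing")


@dataclass
class FlightRecord:
    """Takeoff/landing instants plus a (possibly sparse) altitude trace in feet."""

    flight_id: str
    takeoff: pd.Timestamp
    landing: pd.Timestamp
    altitude_trace: pd.Series  # UTC DatetimeIndex -> altitude_ft

    def __post_init__(self):
        def _utc(ts):
            ts = pd.Timestamp(ts)
            return ts.tz_localize("UTC") if ts.tz is None else ts.tz_convert("UTC")

        self.takeoff = _utc(self.takeoff)
        self.landing = _utc(self.landing)
        if not self.takeoff < self.landing:
            raise ValidationError("takeoff must precede landing")
        if (self.altitude_trace.to_numpy() < 0).any():
            raise ValidationError("altitudes must be >= 0")

    @property
    def duration_hours(self) -> float:
        return (self.landing - self.takeoff).total_seconds() / 3600.0

    @property
    def duration_class(self) -> str:
        h = self.duration_hours
        if h < 2:
            return "short"
        return "medium" if h <= 7 else "long"


@dataclass
class PvtSession:
    """One psychomotor vigilance test: 12 visual stimuli; ``None`` marks a miss."""

    timestamp: pd.Timestamp
    response_times_ms: list
    alertness_label: str = "none"

    def __post_init__(self):
        if self.alertness_label not in ("tired", "alert", "in_between", "none"):
            raise ValidationError(f"unknown alertness label {self.alertness_label!r}")
        if len(self.response_times_ms) > 12:
            raise ValidationError("a PVT session has at most 12 stimuli")


def label_flight_stages(
    spo2: TimeStampedSeries,
    flight: FlightRecord,
    cruise_band: float = 0.95,
    altitude_tolerance_minutes: float = 5.0,
) -> pd.DataFrame:
    """Join SpO2 to altitude and assign one of the five flight stages.

    Samples with no altitude reading within the tolerance get stage
    ``unlabeled``.  Returns a frame indexed by timestamp with columns
    ``spo2_pct``, ``altitude_ft``, ``stage``, ``hours_since_takeoff``.
    """
    trace = flight.altitude_trace
    if len(trace) == 0:
        raise ValidationError("flight has no altitude trace")
    left = pd.DataFrame({"t": spo2.data.index, "spo2_pct": spo2.data.to_numpy()})
    right = pd.DataFrame({"t": trace.index, "altitude_ft": trace.to_numpy()})
    joined = pd.merge_asof(
        left.sort_values("t"),
        right.sort_values("t"),
        on="t",
        direction="nearest",
        tolerance=pd.Timedelta(minutes=altitude_tolerance_minutes),
    )
    threshold = cruise_band * float(trace.max())
    at_cruise = trace[trace >= threshold]
    t_first, t_last = at_cruise.index[0], at_cruise.index[-1]
    t = pd.DatetimeIndex(joined["t"])
    stage = np.full(len(joined), "unlabeled", dtype=object)
    matched = joined["altitude_ft"].notna().to_numpy()
    stage[matched & (t < flight.takeoff)] = "pre_takeoff"
    stage[matched & (t >= flight.takeoff) & (t < t_first)] = "ascent"
    stage[matched & (t >= t_first) & (t <= t_last)] = "cruise"
    stage[matched & (t > t_last) & (t <= flight.landing)] = "descent"
    stage[matched & (t > flight.landing)] = "post_landing"
    hours = (t - flight.takeoff).total_seconds() / 3600.0
    return pd.DataFrame(
        {
            "spo2_pct": joined["spo2_pct"].to_numpy(),
            "altitude_ft": joined["altitude_ft"].to_numpy(),
            "stage": stage,
            "hours_since_takeoff": hours,
        },
        index=t,
    )


def spo2_category_fractions(labeled: pd.DataFrame, by_stage: bool = True) -> pd.DataFrame:
    """Fractions of samples at >=97%, 91-96% and <91% saturation.

    The bins are exhaustive and disjoint for non-integer readings; fractions
    sum to 1 in each row.
    """
    if labeled.empty:
        raise ValidationError("no SpO2 samples")
    spo2 = labeled["spo2_pct"]
    cats = pd.DataFrame(
        {
            "pct_97_100": spo2 >= 97,
            "pct_91_96": (spo2 >= 91) & (spo2 < 97),
            "pct_le_90": spo2 < 91,
        },
        index=labeled.index,
    )
    if by_stage:
        out = cats.groupby(labeled["stage"].to_numpy()).mean()
        out.index.name = "stage"
        order = [s for s in STAGES + ("unlabeled",) if s in out.index]
        return out.loc[order]
    return cats.mean().to_frame(name="overall").T


def spo2_altitude_correlation(labeled: pd.DataFrame):
    """Pearson r (and two-sided p) of SpO2 against altitude."""
    pairs = labeled[["spo2_pct", "altitude_ft"]].dropna()
    if len(pairs) < 3:
        raise UndefinedStatisticError("need >= 3 paired SpO2/altitude samples")
    x, y = pairs["spo2_pct"].to_numpy(), pairs["altitude_ft"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def adaptation_analysis(
    labeled: pd.DataFrame,
    flight: FlightRecord,
    mode: str = "quarters",
    altitude_floor: float = 35000.0,
) -> dict:
    """Late-flight SpO2 adaptation tests at high altitude.

    ``quarters``: split the airborne span into 4 equal quarters, restrict to
    samples at/above ``altitude_floor``, and rank-sum (two-sided Wilcoxon)
    the last quarter against each other quarter.  ``time_bins``: two-sample
    Kolmogorov-Smirnov of samples >7 h after takeoff vs <2 h after takeoff.
    Returns ``{"applicable": False, "reason": ...}`` when a compared bin is
    empty (e.g. short flights).
    """
    air = labeled[
        (labeled.index >= flight.takeoff)
        & (labeled.index <= flight.landing)
        & (labeled["altitude_ft"] >= altitude_floor)
    ]
    if mode == "quarters":
        dur = flight.landing - flight.takeoff
        q = np.minimum(np.asarray((air.index - flight.takeoff) / (dur / 4), dtype=int), 3)
        groups = {k: air["spo2_pct"].to_numpy()[q == k] for k in range(4)}
        last = groups[3]
        others = {k: g for k, g in groups.items() if k < 3 and len(g)}
        if len(last) == 0 or not others:
            return {"mode": mode, "applicable": False, "reason": "empty quarter bins"}
        comparisons = []
        for k, g in others.items():
            stat, p = stats.ranksums(last, g)
            comparisons.append(
                {
                    "quarter": k + 1,
                    "statistic": float(stat),
                    "p_value": float(p),
                    "median": float(np.median(g)),
                }
            )
        return {
            "mode": mode,
            "applicable": True,
            "median_last_quarter": float(np.median(last)),
            "comparisons": comparisons,
            "min_p_value": float(min(c["p_value"] for c in comparisons)),
        }
    if mode == "time_bins":
        late = air["spo2_pct"][air["hours_since_takeoff"] > 7].to_numpy()
        early = air["spo2_pct"][air["hours_since_takeoff"] < 2].to_numpy()
        if len(late) == 0 or len(early) == 0:
            return {"mode": mode, "applicable": False, "reason": "empty time bins"}
        stat, p = stats.ks_2samp(late, early)
        return {
            "mode": mode,
            "applicable": True,
            "median_late": float(np.median(late)),
            "median_early": float(np.median(early)),
            "statistic": float(stat),
            "p_value": float(p),
        }
    raise ValidationError(f"unknown adaptation mode {mode!r}")


def fatigue_spo2_test(samples: pd.DataFrame) -> dict:
    """Two-sample KS comparison of tired vs alert SpO2 distributions.

    ``samples`` needs columns ``spo2_pct`` and ``alertness``.
    """
    tired = samples.loc[samples["alertness"] == "tired", "spo2_pct"].to_numpy()
    alert = samples.loc[samples["alertness"] == "alert", "spo2_pct"].to_numpy()
    if len(tired) == 0 or len(alert) == 0:
        raise UndefinedStatisticError("need both tired and alert samples")
    stat, p = stats.ks_2samp(tired, alert)
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "median_tired": float(np.median(tired)),
        "median_alert": float(np.median(alert)),
        "n_tired": len(tired),
        "n_alert": len(alert),
    }


def summarize_pvt(session: PvtSession) -> float:
    """Mean response time with every miss or value over 500 ms censored to 500."""
    rts = list(session.response_times_ms) + [None] * (12 - len(session.response_times_ms))
    censored = [
        500.0 if (r is None or (isinstance(r, float) and math.isnan(r)) or r > 500) else float(r)
        for r in rts
    ]
    return float(np.mean(censored))


def read_flights_csv(flights_path, altitude_path) -> list:
    """Read ``flight_id,takeoff,landing`` plus ``flight_id,timestamp,altitude_ft``."""
    flights = pd.read_csv(flights_path)
    altitude = pd.read_csv(altitude_path)
    altitude["timestamp"] = pd.to_datetime(altitude["timestamp"], utc=True, format="ISO8601")
    out = []
    for row in flights.itertuples(index=False):
        trace = altitude[altitude["flight_id"] == row.flight_id]
        out.append(
            FlightRecord(
                str(row.flight_id),
                pd.Timestamp(row.takeoff).tz_convert("UTC")
                if pd.Timestamp(row.takeoff).tz is not None
                else pd.Timestamp(row.takeoff, tz="UTC"),
                pd.Timestamp(row.landing).tz_convert("UTC")
                if pd.Timestamp(row.landing).tz is not None
                else pd.Timestamp(row.landing, tz="UTC"),
                pd.Series(
                    trace["altitude_ft"].to_numpy(dtype=float),
                    index=pd.DatetimeIndex(trace["timestamp"]),
                ),
            )
        )
    return out
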