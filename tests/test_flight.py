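"""Flight-stage labeling, SpO2 summaries and fatigue/PVT analyses."""

import numpy as np
import pandas as pd
import pytest

import cohwear as cw
from cohwear import UndefinedStatisticError

from conftest import utc_minutes


def _trapezoid_flight(duration_h=4.0, cruise_alt=36000.0):
    takeoff = pd.Timestamp("2020-05-01 12:00", tz="UTC")
    landing = takeoff + pd.Timedelta(hours=duration_h)
    dur_min = duration_h * 60
    t = pd.date_range(takeoff, landing, freq="2min")
    m = (t - takeoff).total_seconds() / 60
    alt = cruise_alt * np.minimum(np.clip(m / 25, 0, 1), np.clip((dur_min - m) / 25, 0, 1))
    return cw.FlightRecord("f1", takeoff, landing, pd.Series(alt, index=t))


def _spo2_over(flight, pad_min=30, value=95.0):
    start = flight.takeoff - pd.Timedelta(minutes=pad_min)
    n = int((flight.landing - start).total_seconds() / 60) + pad_min
    return cw.TimeStampedSeries("p1", "masimo", "spo2_pct", utc_minutes(str(start), [value] * n))


class TestLabelFlightStages:
    def test_trapezoidal_profile_gives_five_ordered_stages(self):
        flight = _trapezoid_flight()
        spo2 = _spo2_over(flight)
        labeled = cw.label_flight_stages(spo2, flight)
        stages = [s for s in labeled["stage"] if s != "unlabeled"]
        seen = list(dict.fromkeys(stages))
        assert seen == list(cw.flight.STAGES)
        order = {s: i for i, s in enumerate(cw.flight.STAGES)}
        ranks = [order[s] for s in stages]
        assert ranks == sorted(ranks)

    def test_ground_only_trace_is_pre_and_post(self):
        takeoff = pd.Timestamp("2020-05-01 12:00", tz="UTC")
        flight = cw.FlightRecord(
            "f2", takeoff, takeoff + pd.Timedelta(hours=1),
            pd.Series([0.0, 0.0], index=pd.DatetimeIndex([takeoff, takeoff + pd.Timedelta(hours=1)])),
        )
        spo2 = _spo2_over(flight)
        labeled = cw.label_flight_stages(spo2, flight)
        # samples near the trace are pre/post; those beyond the 5-min
        # altitude-join tolerance are flagged unlabeled
        near_pre = (labeled.index < takeoff) & (labeled.index >= takeoff - pd.Timedelta(minutes=5))
        far_pre = labeled.index < takeoff - pd.Timedelta(minutes=5)
        assert (labeled.loc[near_pre, "stage"] == "pre_takeoff").all()
        assert (labeled.loc[far_pre, "stage"] == "unlabeled").all()
        near_post = (labeled.index > flight.landing) & (
            labeled.index <= flight.landing + pd.Timedelta(minutes=5)
        )
        assert (labeled.loc[near_post, "stage"] == "post_landing").all()

    def test_samples_without_nearby_altitude_flagged(self):
        flight = _trapezoid_flight()
        far = flight.landing + pd.Timedelta(hours=3)
        spo2 = cw.TimeStampedSeries("p1", "m", "spo2_pct", utc_minutes(str(far), [96.0] * 5))
        labeled = cw.label_flight_stages(spo2, flight)
        assert (labeled["stage"] == "unlabeled").all()

    def test_boundaries_match_threshold_scan(self):
        rng = np.random.default_rng(5)
        flight = _trapezoid_flight(duration_h=5.0)
        trace = flight.altitude_trace + rng.normal(0, 300, len(flight.altitude_trace))
        trace = trace.clip(lower=0.0)
        noisy = cw.FlightRecord("f3", flight.takeoff, flight.landing, trace)
        spo2 = _spo2_over(noisy)
        labeled = cw.label_flight_stages(spo2, noisy)
        thr = 0.95 * trace.max()
        at = trace[trace >= thr]
        t_first, t_last = at.index[0], at.index[-1]
        cruise = labeled[labeled["stage"] == "cruise"]
        assert cruise.index.min() >= t_first - pd.Timedelta(minutes=1)
        assert cruise.index.max() <= t_last


class TestSpo2CategoryFractions:
    def _labeled(self, spo2_values):
        idx = pd.date_range("2020-05-01", periods=len(spo2_values), freq="min", tz="UTC")
        return pd.DataFrame(
            {"spo2_pct": spo2_values, "altitude_ft": 0.0, "stage": "cruise",
             "hours_since_takeoff": 1.0},
            index=idx,
        )

    def test_all_high(self):
        out = cw.spo2_category_fractions(self._labeled([98.0] * 10))
        assert out.loc["cruise"].tolist() == [1.0, 0.0, 0.0]

    def test_category_boundaries(self):
        out = cw.spo2_category_fractions(self._labeled([97.0, 91.0, 90.0]))
        assert out.loc["cruise"].tolist() == pytest.approx([1 / 3, 1 / 3, 1 / 3])

    def test_fractions_sum_to_one_and_match_counting(self):
        rng = np.random.default_rng(9)
        values = rng.uniform(85, 100, 1000)
        out = cw.spo2_category_fractions(self._labeled(values))
        assert out.loc["cruise"].sum() == pytest.approx(1.0, abs=1e-12)
        assert out.loc["cruise", "pct_97_100"] == pytest.approx(np.mean(values >= 97))
        assert out.loc["cruise", "pct_91_96"] == pytest.approx(np.mean((values >= 91) & (values < 97)))
        assert out.loc["cruise", "pct_le_90"] == pytest.approx(np.mean(values < 91))


class TestSpo2AltitudeCorrelation:
    def _labeled(self, spo2, alt):
        idx = pd.date_range("2020-05-01", periods=len(spo2), freq="min", tz="UTC")
        return pd.DataFrame(
            {"spo2_pct": spo2, "altitude_ft": alt, "stage": "cruise", "hours_since_takeoff": 1.0},
            index=idx,
        )

    def test_exact_linear_relation_gives_minus_one(self):
        alt = np.linspace(0, 36000, 50)
        r, p = cw.spo2_altitude_correlation(self._labeled(100 - alt / 10000, alt))
        assert r == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(31)
        r, _ = cw.spo2_altitude_correlation(
            self._labeled(rng.normal(95, 1, 1000), rng.uniform(0, 36000, 1000))
        )
        assert abs(r) < 0.1

    def test_five_point_hand_computation(self):
        spo2 = np.array([98.0, 97.0, 95.0, 93.0, 92.0])
        alt = np.array([0.0, 10000.0, 20000.0, 30000.0, 36000.0])
        r, _ = cw.spo2_altitude_correlation(self._labeled(spo2, alt))
        sx, sy = spo2 - spo2.mean(), alt - alt.mean()
        expected = float((sx * sy).sum() / np.sqrt((sx**2).sum() * (sy**2).sum()))
        assert r == pytest.approx(expected)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            cw.spo2_altitude_correlation(self._labeled([95.0] * 10, [36000.0] * 10))


class TestAdaptationAnalysis:
    def test_flat_spo2_reports_null(self):
        flight = _trapezoid_flight(duration_h=10.0)
        spo2 = _spo2_over(flight, value=93.0)
        labeled = cw.label_flight_stages(spo2, flight)
        report = cw.adaptation_analysis(labeled, flight, mode="quarters")
        assert report["applicable"]
        assert report["median_last_quarter"] == 93.0
        assert report["min_p_value"] > 0.9

    def test_injected_last_quarter_ramp_detected(self):
        flight = _trapezoid_flight(duration_h=10.0)
        spo2 = _spo2_over(flight, value=93.0)
        rng = np.random.default_rng(3)
        vals = spo2.data.to_numpy() + rng.normal(0, 0.5, len(spo2.data))
        t = spo2.data.index
        last_q = t >= flight.takeoff + 0.75 * (flight.landing - flight.takeoff)
        vals[last_q & (t <= flight.landing)] += 2.0
        bumped = spo2.with_data(pd.Series(np.clip(vals, 0, 100), index=t))
        labeled = cw.label_flight_stages(bumped, flight)
        report = cw.adaptation_analysis(labeled, flight, mode="quarters")
        assert report["applicable"]
        others = [c["median"] for c in report["comparisons"]]
        assert report["median_last_quarter"] - max(others) == pytest.approx(2.0, abs=0.5)
        assert report["min_p_value"] < 0.05

    def test_short_flight_time_bins_not_applicable(self):
        flight = _trapezoid_flight(duration_h=4.0)
        spo2 = _spo2_over(flight)
        labeled = cw.label_flight_stages(spo2, flight)
        report = cw.adaptation_analysis(labeled, flight, mode="time_bins")
        assert report["applicable"] is False


class TestFatigueSpo2:
    def test_identical_distributions_zero_statistic(self):
        df = pd.DataFrame({"spo2_pct": [94.0, 95.0, 96.0] * 2, "alertness": ["tired"] * 3 + ["alert"] * 3})
        out = cw.fatigue_spo2_test(df)
        assert out["statistic"] == 0.0

    def test_shifted_distribution_detected(self):
        rng = np.random.default_rng(6)
        alert = rng.normal(96, 1, 200)
        tired = rng.normal(93, 1, 200)
        df = pd.DataFrame(
            {"spo2_pct": np.concatenate([alert, tired]),
             "alertness": ["alert"] * 200 + ["tired"] * 200}
        )
        out = cw.fatigue_spo2_test(df)
        assert out["median_tired"] < out["median_alert"]
        assert out["p_value"] < 1e-3

    def test_three_point_hand_computed_ks(self):
        df = pd.DataFrame(
            {"spo2_pct": [90.0, 91.0, 92.0, 93.0, 94.0, 95.0],
             "alertness": ["tired"] * 3 + ["alert"] * 3}
        )
        out = cw.fatigue_spo2_test(df)
        assert out["statistic"] == pytest.approx(1.0)  # fully separated CDFs

    def test_single_class_rejected(self):
        df = pd.DataFrame({"spo2_pct": [94.0], "alertness": ["tired"]})
        with pytest.raises(UndefinedStatisticError):
            cw.fatigue_spo2_test(df)


class TestSummarizePvt:
    def _session(self, rts):
        return cw.PvtSession(pd.Timestamp("2020-05-01 12:00", tz="UTC"), rts)

    def test_all_fast_responses(self):
        assert cw.summarize_pvt(self._session([200.0] * 12)) == 200.0

    def test_miss_censored_to_500(self):
        out = cw.summarize_pvt(self._session([300.0] * 11 + [None]))
        assert out == pytest.approx((11 * 300 + 500) / 12)

    def test_slow_responses_censored(self):
        out = cw.summarize_pvt(self._session([650.0] * 12))
        assert out == 500.0

    def test_matches_brute_force_censored_mean(self):
        rng = np.random.default_rng(14)
        for _ in range(30):
            raw = [None if rng.random() < 0.2 else float(rng.uniform(150, 700)) for _ in range(12)]
            expected = np.mean([500.0 if (r is None or r > 500) else r for r in raw])
            assert cw.summarize_pvt(self._session(raw)) == pytest.approx(expected)
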