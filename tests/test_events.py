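"""Positive/negative window construction, scoring and ROC evaluation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import cohwear as cw
from cohwear import UndefinedStatisticError

from _oracles import mann_whitney_auc
from conftest import utc_minutes


def _d(day: int) -> dt.date:
    return dt.date(2020, 1, 1) + dt.timedelta(days=day - 1)


class TestBuildPositiveWindows:
    def test_symptom_span_extended_three_days(self):
        wins = cw.build_positive_windows([(_d(10), _d(12))])
        assert len(wins) == 1
        assert (wins[0].start_date, wins[0].end_date) == (_d(7), _d(12))
        assert wins[0].provenance == "symptom"

    def test_no_annotations_no_windows(self):
        assert cw.build_positive_windows([], []) == []

    def test_high_crp_date_becomes_window(self):
        wins = cw.build_positive_windows([], [(_d(20), 24.8)])
        assert len(wins) == 1
        assert (wins[0].start_date, wins[0].end_date) == (_d(17), _d(20))
        assert wins[0].provenance == "crp_high"

    def test_normal_crp_ignored(self):
        assert cw.build_positive_windows([], [(_d(20), 0.5)]) == []

    @given(st.lists(st.tuples(st.integers(1, 40), st.integers(0, 5)), max_size=6))
    def test_overlapping_windows_merge_to_interval_union(self, spans):
        symptom_spans = [(_d(a), _d(a + l)) for a, l in spans]
        wins = cw.build_positive_windows(symptom_spans)
        got = {day for w in wins for day in w.dates()}
        expected = set()
        for a, l in spans:
            for k in range(-3, l + 1):
                expected.add(_d(a + k))
        assert got == expected
        # windows are maximal runs: pairwise disjoint and non-adjacent
        ordered = sorted(wins, key=lambda w: w.start_date)
        for w1, w2 in zip(ordered, ordered[1:]):
            assert (w2.start_date - w1.end_date).days > 1


class TestBuildNegativeWindows:
    def test_complement_tiling_drops_short_final_tile(self):
        positives = [cw.EventWindow(_d(7), _d(12), "positive", "symptom")]
        negs = cw.build_negative_windows(
            "complement", (_d(1), _d(20)), positives, window_len_days=6
        )
        assert [(w.start_date, w.end_date) for w in negs] == [
            (_d(1), _d(6)),
            (_d(13), _d(18)),  # D19-D20 dropped: shorter than half a tile
        ]

    def test_all_days_positive_warns_and_returns_empty(self):
        positives = [cw.EventWindow(_d(1), _d(10), "positive", "symptom")]
        with pytest.warns(UserWarning, match="empty"):
            negs = cw.build_negative_windows(
                "complement", (_d(1), _d(10)), positives, window_len_days=3
            )
        assert negs == []

    def test_crp_normal_single_day_window(self):
        negs = cw.build_negative_windows(
            "crp_normal", (_d(1), _d(20)), [], crp=[(_d(5), 0.5)], window_len_days=1
        )
        assert [(w.start_date, w.end_date) for w in negs] == [(_d(5), _d(5))]
        assert negs[0].provenance == "crp_normal"

    def test_crp_normal_windows_avoid_positive_days(self):
        positives = [cw.EventWindow(_d(6), _d(8), "positive", "symptom")]
        negs = cw.build_negative_windows(
            "crp_normal", (_d(1), _d(20)), positives, crp=[(_d(5), 0.4)], window_len_days=5
        )
        days = {day for w in negs for day in w.dates()}
        assert days == {_d(3), _d(4), _d(5)}

    def test_default_window_length_is_median_positive_length(self):
        positives = [
            cw.EventWindow(_d(1), _d(4), "positive", "symptom"),   # 4 days
            cw.EventWindow(_d(10), _d(15), "positive", "symptom"),  # 6 days
        ]
        negs = cw.build_negative_windows("complement", (_d(1), _d(30)), positives)
        lengths = {(w.end_date - w.start_date).days + 1 for w in negs[:-1]}
        assert lengths == {5}

    @given(st.integers(1, 9), st.integers(10, 35))
    def test_complement_tiles_match_tiling_oracle(self, w, span_days):
        positives = [cw.EventWindow(_d(7), _d(12), "positive", "symptom")]
        negs = cw.build_negative_windows(
            "complement", (_d(1), _d(span_days)), positives, window_len_days=w
        )
        pos_days = set(positives[0].dates())
        for win in negs:
            days = win.dates()
            assert len(days) <= w
            assert 2 * len(days) >= w
            assert not (set(days) & pos_days)
        # tiles cover the complement except possibly a dropped short tail per run
        covered = {day for win in negs for day in win.dates()}
        free = [ _d(k) for k in range(1, span_days + 1) if _d(k) not in pos_days ]
        assert len(set(free) - covered) <= 2 * max(1, (w - 1) // 2)


class TestScoreEventWindows:
    def _peak(self, ts: str) -> cw.Peak:
        t = pd.Timestamp(ts, tz="UTC")
        return cw.Peak(t, 3.0, 3.0, t, t)

    def test_window_containing_peak_is_hit(self):
        smoothed = utc_minutes("2020-01-01", np.zeros(1440 * 5))
        windows = [cw.EventWindow(_d(2), _d(3), "positive", "symptom")]
        scored = cw.score_event_windows(windows, [self._peak("2020-01-02 10:00")], smoothed)
        assert bool(scored["binary_hit"].iloc[0])

    def test_window_over_zero_region_scores_zero(self):
        smoothed = utc_minutes("2020-01-01", np.zeros(1440 * 5))
        windows = [cw.EventWindow(_d(2), _d(3), "negative", "complement")]
        scored = cw.score_event_windows(windows, [], smoothed)
        assert not bool(scored["binary_hit"].iloc[0])
        assert scored["score"].iloc[0] == 0.0

    def test_window_without_data_flagged_minus_inf(self):
        smoothed = utc_minutes("2020-01-01", np.zeros(1440))
        windows = [cw.EventWindow(_d(10), _d(11), "negative", "complement")]
        scored = cw.score_event_windows(windows, [], smoothed)
        assert bool(scored["flagged"].iloc[0])
        assert scored["score"].iloc[0] == float("-inf")

    def test_hits_match_brute_force_containment(self):
        rng = np.random.default_rng(17)
        smoothed = utc_minutes("2020-01-01", rng.normal(0, 1, 1440 * 40))
        peak_times = [
            pd.Timestamp("2020-01-01", tz="UTC") + pd.Timedelta(minutes=int(m))
            for m in rng.integers(0, 1440 * 40, 12)
        ]
        peaks = [cw.Peak(t, 2.5, 2.5, t, t) for t in peak_times]
        windows = [
            cw.EventWindow(_d(1 + 4 * k), _d(3 + 4 * k), "negative", "complement")
            for k in range(9)
        ]
        scored = cw.score_event_windows(windows, peaks, smoothed)
        for row in scored.itertuples():
            expected = any(row.start_date <= t.date() <= row.end_date for t in peak_times)
            assert row.binary_hit == expected
            in_win = [
                v
                for t, v in smoothed.items()
                if row.start_date <= t.date() <= row.end_date
            ]
            assert row.score == pytest.approx(max(in_win))


class TestRocCurveAuc:
    def _scored(self, pos, neg):
        rows = [{"label": "positive", "score": s} for s in pos]
        rows += [{"label": "negative", "score": s} for s in neg]
        return pd.DataFrame(rows)

    def test_perfect_separation(self):
        roc = cw.roc_curve_auc(self._scored([3.0, 4.0], [0.0, 1.0]))
        assert roc.auc == 1.0

    def test_all_scores_equal_is_chance(self):
        roc = cw.roc_curve_auc(self._scored([1.0, 1.0], [1.0, 1.0, 1.0]))
        assert roc.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            cw.roc_curve_auc(self._scored([1.0, 2.0], []))

    @given(
        st.lists(st.floats(-5, 5, allow_nan=False, width=16), min_size=1, max_size=25),
        st.lists(st.floats(-5, 5, allow_nan=False, width=16), min_size=1, max_size=25),
    )
    def test_auc_equals_mann_whitney_closed_form(self, pos, neg):
        roc = cw.roc_curve_auc(self._scored(pos, neg))
        assert roc.auc == pytest.approx(mann_whitney_auc(pos, neg), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        pos = list(rng.normal(1.0, 1.0, 30))
        neg = list(rng.normal(0.0, 1.0, 40))
        base = cw.roc_curve_auc(self._scored(pos, neg)).auc
        warped = cw.roc_curve_auc(
            self._scored([np.expm1(s) for s in pos], [np.expm1(s) for s in neg])
        ).auc
        assert warped == pytest.approx(base, abs=1e-12)

    def test_threshold_two_operating_point_matches_binary_rule(self):
        """Sweeping the continuous score reproduces the binary peak rule at
        the default height threshold on clean, well-separated signal."""
        values = np.zeros(1440 * 30)
        for c in (5000, 20000, 36000):
            values[c - 300: c + 300] = 3.0
        z = utc_minutes("2020-01-01", values)
        det = cw.CohDetector().fit(z)
        pos = [cw.EventWindow(_d(4), _d(5), "positive", "symptom"),
               cw.EventWindow(_d(14), _d(15), "positive", "symptom"),
               cw.EventWindow(_d(25), _d(26), "positive", "symptom")]
        neg = [cw.EventWindow(_d(8), _d(11), "negative", "complement"),
               cw.EventWindow(_d(18), _d(21), "negative", "complement")]
        scored = cw.score_event_windows(pos + neg, det.peaks_, det.smoothed_)
        roc = cw.roc_curve_auc(scored)
        # TPR/FPR at threshold 2 equal the binary-hit rates
        k = int(np.argmin(np.abs(roc.thresholds - 2.0)))
        pos_rows = scored[scored["label"] == "positive"]
        neg_rows = scored[scored["label"] == "negative"]
        at_thr = (pos_rows["score"] >= roc.thresholds[k]).mean()
        assert roc.tpr[k] == pytest.approx(at_thr)
        assert roc.tpr[k] == pytest.approx(pos_rows["binary_hit"].mean())
        assert roc.fpr[k] == pytest.approx(neg_rows["binary_hit"].mean())
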