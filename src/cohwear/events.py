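"""Positive/negative event windows and ROC evaluation of the COH detector.

Positive (illness) windows come from self-reported symptom spans and
high-CRP blood tests, each extended 3 days earlier to acknowledge that the
physiological signal can precede the report.  Negative (control) windows
are built either from normal-CRP measurement days or as the tiled
complement of the positives over the monitoring span.  Each window is
scored two ways: a binary hit (>= 1 retained peak inside the window) and a
continuous score (the maximum smoothed z inside the window, the quantity
the peak-height threshold operates on), so that sweeping the continuous
score yields an ROC curve whose threshold-2 operating point reproduces the
binary rule.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from ._errors import UndefinedStatisticError, ValidationError

_DAY = _dt.timedelta(days=1)


@dataclass
class CrpBands:
    """CRP interpretation bands in mg/L (configurable per participant)."""

    high: float = 10.0
    intermediate: float = 3.0
    normal_below: float = 3.0

    def __post_init__(self):
        if self.intermediate > self.high:
            raise ValidationError("intermediate band must not exceed high band")


@dataclass(frozen=True)
class EventWindow:
    """A labeled day span, inclusive on both ends."""

    start_date: _dt.date
    end_date: _dt.date
    label: str  # positive | negative
    provenance: str  # symptom | crp_high | crp_normal | complement

    def __post_init__(self):
        if self.start_date > self.end_date:
            raise ValidationError("window start after end")

    def dates(self) -> list:
        n = (self.end_date - self.start_date).days + 1
        return [self.start_date + k * _DAY for k in range(n)]


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr})

    def summary(self) -> dict:
        return {"auc": float(self.auc), "n_pos": self.n_pos, "n_neg": self.n_neg}


def _as_crp_pairs(crp):
    """Normalize CRP input (DataFrame with date/value, or iterable of pairs)."""
    if crp is None:
        return []
    if isinstance(crp, pd.DataFrame):
        return list(zip(crp["date"], crp["value"]))
    return list(crp)


def _runs_to_windows(dates: set, label: str, provenance_of=None, default_prov: str = "complement"):
    windows = []
    if not dates:
        return windows
    ordered = sorted(dates)
    start = prev = ordered[0]
    runs = []
    for d in ordered[1:]:
        if (d - prev).days > 1:
            runs.append((start, prev))
            start = d
        prev = d
    runs.append((start, prev))
    for s, e in runs:
        if provenance_of is not None:
            provs = {provenance_of[d] for d in _span_dates(s, e) if d in provenance_of}
            prov = "symptom" if "symptom" in provs else next(iter(provs), default_prov)
        else:
            prov = default_prov
        windows.append(EventWindow(s, e, label, prov))
    return windows


def _span_dates(start: _dt.date, end: _dt.date):
    n = (end - start).days + 1
    return [start + k * _DAY for k in range(n)]


def build_positive_windows(
    symptom_spans,
    crp=None,
    bands: CrpBands | None = None,
    lead_days: int = 3,
) -> list:
    """Positive windows from symptom spans and high-CRP dates, each extended
    ``lead_days`` earlier; overlapping/adjacent extended spans are merged."""
    bands = bands or CrpBands()
    dates: set = set()
    prov: dict = {}
    for start, end in symptom_spans:
        for d in _span_dates(start - lead_days * _DAY, end):
            dates.add(d)
            prov[d] = "symptom"
    for d, value in _as_crp_pairs(crp):
        if value > bands.high:
            for day in _span_dates(d - lead_days * _DAY, d):
                dates.add(day)
                prov.setdefault(day, "crp_high")
    return _runs_to_windows(dates, "positive", provenance_of=prov)


def build_negative_windows(
    mode: str,
    monitoring_span,
    positives,
    crp=None,
    bands: CrpBands | None = None,
    window_len_days: int | None = None,
) -> list:
    """Control windows, disjoint from the positives.

    ``crp_normal``: one window of ``window_len_days`` centered on each
    normal-CRP measurement, clipped to the monitoring span and to exclude
    positive days.  ``complement``: the complement of the positive days
    tiled into consecutive windows of ``window_len_days`` (a final partial
    tile is kept when at least half the nominal length).  When
    ``window_len_days`` is omitted it defaults to the median positive-window
    length.
    """
    bands = bands or CrpBands()
    span_start, span_end = monitoring_span
    if window_len_days is None:
        lengths = sorted((w.end_date - w.start_date).days + 1 for w in positives)
        if not lengths:
            raise ValidationError("window_len_days required when there are no positives")
        window_len_days = int(round(float(np.median(lengths))))
    w = max(int(window_len_days), 1)
    pos_dates = {d for win in positives for d in win.dates()}
    negatives = []
    if mode == "complement":
        free = [d for d in _span_dates(span_start, span_end) if d not in pos_dates]
        for run in _runs_to_windows(set(free), "negative"):
            days = run.dates()
            for k in range(0, len(days), w):
                tile = days[k: k + w]
                if len(tile) * 2 >= w:
                    negatives.append(EventWindow(tile[0], tile[-1], "negative", "complement"))
    elif mode == "crp_normal":
        seen = set()
        for d, value in _as_crp_pairs(crp):
            if value < bands.normal_below:
                lo = d - ((w - 1) // 2) * _DAY
                hi = d + (w // 2) * _DAY
                days = {
                    day
                    for day in _span_dates(lo, hi)
                    if span_start <= day <= span_end and day not in pos_dates
                }
                for win in _runs_to_windows(days, "negative", default_prov="crp_normal"):
                    key = (win.start_date, win.end_date)
                    if key not in seen:
                        seen.add(key)
                        negatives.append(win)
    else:
        raise ValidationError(f"unknown negative mode {mode!r}")
    if not negatives:
        warnings.warn("negative window set is empty", stacklevel=2)
    return negatives


def score_event_windows(windows, peaks, smoothed: pd.Series) -> pd.DataFrame:
    """Score disjoint windows against retained peaks and the smoothed signal.

    ``binary_hit`` is True when a retained peak's day falls inside the
    window; ``score`` is the maximum smoothed z inside the window (-inf and
    flagged when the window holds no smoothed data).
    """
    pos_dates = {d for win in windows if win.label == "positive" for d in win.dates()}
    for win in windows:
        if win.label == "negative" and any(d in pos_dates for d in win.dates()):
            raise ValidationError("positive and negative windows overlap")
    peak_days = np.array(sorted({pk.time.tz_convert("UTC").date() for pk in peaks}))
    smooth_days = smoothed.index.tz_convert("UTC").date if len(smoothed) else np.array([])
    rows = []
    for win in windows:
        hit = bool(peak_days.size) and bool(
            np.any((peak_days >= win.start_date) & (peak_days <= win.end_date))
        )
        if len(smoothed):
            inside = (smooth_days >= win.start_date) & (smooth_days <= win.end_date)
            vals = smoothed.to_numpy()[inside]
        else:
            vals = np.array([])
        flagged = vals.size == 0
        score = float(np.max(vals)) if vals.size else float("-inf")
        rows.append(
            {
                "start_date": win.start_date,
                "end_date": win.end_date,
                "label": win.label,
                "provenance": win.provenance,
                "binary_hit": hit,
                "score": score,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def roc_curve_auc(scored: pd.DataFrame) -> RocResult:
    """ROC over the continuous window scores; AUC by the trapezoid rule.

    Ties step diagonally (simultaneous TPR/FPR step).  Raises when only one
    class is present among windows with finite scores.
    """
    finite = scored[np.isfinite(scored["score"])]
    y = (finite["label"] == "positive").to_numpy()
    if y.all() or not y.any() or len(finite) == 0:
        raise UndefinedStatisticError("ROC needs at least one positive and one negative window")
    scores = finite["score"].to_numpy(dtype=float)
    fpr, tpr, thresholds = _sk_roc_curve(y.astype(int), scores, drop_intermediate=False)
    return RocResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=float(_trapezoid_auc(fpr, tpr)),
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
    )


def read_annotations_csv(path):
    """Read the ``date,kind,value`` annotation dialect.

    Returns ``(symptom_spans, crp_pairs)`` where kinds ``symptom_start`` /
    ``symptom_end`` are paired in order and ``crp_mg_per_l`` rows carry the
    measurement value.
    """
    frame = pd.read_csv(path)
    frame["date"] = pd.to_datetime(frame["date"]).dt.date
    crp = [
        (d, float(v))
        for d, v in frame.loc[frame["kind"] == "crp_mg_per_l", ["date", "value"]].itertuples(index=False)
    ]
    starts = list(frame.loc[frame["kind"] == "symptom_start", "date"])
    ends = list(frame.loc[frame["kind"] == "symptom_end", "date"])
    if len(starts) != len(ends):
        raise ValidationError("unpaired symptom_start/symptom_end annotations")
    spans = list(zip(starts, ends))
    for s, e in spans:
        if s > e:
            raise ValidationError(f"symptom span starts {s} after end {e}")
    return spans, crp
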