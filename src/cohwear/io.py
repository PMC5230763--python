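"""CSV I/O for wearable datasets.

Dialect (RFC-4180, UTF-8, mandatory header):

* ``streams.csv`` — long format ``participant_id,device_id,channel,timestamp,value``
  with ISO-8601 timestamps carrying an offset; converted to UTC on load.
* ``sleep.csv`` — ``start,end,label`` with label in {sleep, wake}.
* ``activities.csv`` — ``start,end,label,source``.
* ``meta.yaml`` — ``home_timezone``.

Rows whose value fails the channel's physiologic bounds are dropped and
reported; malformed timestamps and duplicate or non-monotone timestamps
within a channel are hard errors naming the offending row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._errors import ParseError, ValidationError
from .streams import (
    ActivityInterval,
    SleepWakeTrack,
    TimeStampedSeries,
    WearableDataset,
    value_in_bounds,
)

STREAM_COLUMNS = ["participant_id", "device_id", "channel", "timestamp", "value"]


@dataclass
class LoadReport:
    """What happened while loading a dataset."""

    n_rows_read: int = 0
    n_rows_dropped: int = 0
    messages: list = field(default_factory=list)


def _parse_timestamps(raw: pd.Series, filename: str) -> pd.DatetimeIndex:
    parsed = pd.to_datetime(raw, errors="coerce", utc=True, format="ISO8601")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        # +2: 1-based with header line
        raise ParseError(f"{filename}: malformed timestamp {raw.iloc[row]!r} at line {row + 2}")
    return pd.DatetimeIndex(parsed)


def read_streams_csv(path, report: LoadReport | None = None) -> list:
    """Read a long-format stream CSV into a list of TimeStampedSeries."""
    path = Path(path)
    report = report if report is not None else LoadReport()
    frame = pd.read_csv(path, dtype={"participant_id": str, "device_id": str, "channel": str})
    missing = [c for c in STREAM_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path.name}: missing columns {missing}")
    report.n_rows_read += len(frame)
    if frame.empty:
        return []
    ts = _parse_timestamps(frame["timestamp"], path.name)
    frame = frame.assign(timestamp=ts)
    out = []
    for (pid, dev, chan), grp in frame.groupby(
        ["participant_id", "device_id", "channel"], sort=True
    ):
        values = grp["value"].to_numpy(dtype=float)
        keep = value_in_bounds(chan, values) & ~np.isnan(values)
        if not keep.all():
            n_bad = int((~keep).sum())
            report.n_rows_dropped += n_bad
            report.messages.append(
                f"{path.name}: dropped {n_bad} out-of-range/NaN value(s) for {chan}/{dev}"
            )
        grp = grp.loc[keep]
        data = pd.Series(grp["value"].to_numpy(dtype=float), index=pd.DatetimeIndex(grp["timestamp"]))
        out.append(TimeStampedSeries(pid, dev, chan, data))
    return out


def _read_intervals_csv(path) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path)
    for col in ("start", "end"):
        frame[col] = _parse_timestamps(frame[col], path.name)
    return frame


def read_dataset(path, report: LoadReport | None = None) -> WearableDataset:
    """Load a dataset from a stream CSV file or a dataset directory.

    A directory is expected to hold ``streams.csv`` plus optional
    ``sleep.csv``, ``activities.csv`` and ``meta.yaml``.
    """
    path = Path(path)
    report = report if report is not None else LoadReport()
    if path.is_dir():
        streams = read_streams_csv(path / "streams.csv", report)
        sleep = None
        sleep_path = path / "sleep.csv"
        if sleep_path.exists():
            frame = _read_intervals_csv(sleep_path)
            sleep = SleepWakeTrack(
                [(s, e, lab) for s, e, lab in frame[["start", "end", "label"]].itertuples(index=False)]
            )
        activities = []
        act_path = path / "activities.csv"
        if act_path.exists():
            frame = _read_intervals_csv(act_path)
            if "source" not in frame.columns:
                frame["source"] = "log"
            activities = [
                ActivityInterval(s, e, lab, src)
                for s, e, lab, src in frame[["start", "end", "label", "source"]].itertuples(index=False)
            ]
        home_tz = "UTC"
        meta_path = path / "meta.yaml"
        if meta_path.exists():
            meta = yaml.safe_load(meta_path.read_text()) or {}
            home_tz = meta.get("home_timezone", "UTC")
        return WearableDataset(streams, sleep=sleep, activities=activities, home_timezone=home_tz)
    streams = read_streams_csv(path, report)
    return WearableDataset(streams)


def _iso(ts: pd.Timestamp) -> str:
    return ts.tz_convert("UTC").isoformat()


def write_dataset(dataset: WearableDataset, path) -> None:
    """Write a dataset directory in the same dialect ``read_dataset`` accepts."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in dataset.streams:
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "device_id": s.device_id,
                    "channel": s.channel,
                    "timestamp": [_iso(t) for t in s.data.index],
                    "value": s.data.to_numpy(),
                }
            )
        )
    frame = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=STREAM_COLUMNS)
    )
    frame.to_csv(path / "streams.csv", index=False)
    if dataset.sleep is not None:
        pd.DataFrame(
            [(_iso(s), _iso(e), st) for s, e, st in dataset.sleep.intervals],
            columns=["start", "end", "label"],
        ).to_csv(path / "sleep.csv", index=False)
    if dataset.activities:
        pd.DataFrame(
            [(_iso(a.start), _iso(a.end), a.label, a.source) for a in dataset.activities],
            columns=["start", "end", "label", "source"],
        ).to_csv(path / "activities.csv", index=False)
    (path / "meta.yaml").write_text(yaml.safe_dump({"home_timezone": dataset.home_timezone}))
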