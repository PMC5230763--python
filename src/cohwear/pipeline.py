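"""End-to-end orchestration: load -> resample -> mask -> z -> daily fractions
-> smooth -> peaks -> windows -> scores -> ROC, with all intermediates
written as CSV and a JSON run report.  Deterministic for a fixed config."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._errors import CohwearError, ValidationError
from .detect import CohDetector, CohParams, peaks_to_frame
from .events import (
    CrpBands,
    build_negative_windows,
    build_positive_windows,
    read_annotations_csv,
    roc_curve_auc,
    score_event_windows,
)
from .io import read_dataset
from .normalize import (
    NormParams,
    RestingZScorer,
    write_daily_outliers_csv,
    write_resting_z_csv,
)


@dataclass
class PipelineConfig:
    data_dir: str = ""
    annotations: str = ""
    channel: str = "heart_rate_bpm"
    norm: NormParams = field(default_factory=NormParams)
    coh: CohParams = field(default_factory=CohParams)
    bands: CrpBands = field(default_factory=CrpBands)
    negatives_mode: str = "complement"
    window_len_days: int | None = None
    lead_days: int = 3
    out_dir: str = "cohwear-out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, typ in (("norm", NormParams), ("coh", CohParams), ("bands", CrpBands)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        return cls(**kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full illness-detection pipeline; returns the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        dataset = read_dataset(config.data_dir)
        if not dataset.streams:
            raise ValidationError("dataset contains no streams")

        stage = "normalize"
        scorer = RestingZScorer(channel=config.channel, **_norm_kwargs(config.norm))
        z = scorer.fit(dataset).z_
        write_resting_z_csv(z, out / "resting_z.csv")
        daily = scorer.daily_outliers()
        write_daily_outliers_csv(daily, out / "daily_outliers.csv")

        stage = "detect"
        detector = CohDetector(**asdict(config.coh))
        detector.fit(z)
        peaks_to_frame(detector.peaks_).to_csv(out / "peaks.csv", index=False)

        report = {
            "participant_id": dataset.participant_id,
            "n_days": int(len(daily)),
            "n_resting_minutes": int(len(z)),
            "n_peaks": len(detector.peaks_),
        }

        if config.annotations:
            stage = "evaluate"
            spans, crp = read_annotations_csv(config.annotations)
            positives = build_positive_windows(spans, crp, config.bands, config.lead_days)
            days = z.index.tz_convert("UTC").date
            span = (days.min(), days.max())
            negatives = build_negative_windows(
                config.negatives_mode, span, positives, crp, config.bands,
                config.window_len_days,
            )
            scored = score_event_windows(positives + negatives, detector.peaks_, detector.smoothed_)
            scored.to_csv(out / "windows_scored.csv", index=False)
            roc = roc_curve_auc(scored)
            roc.to_frame().to_csv(out / "roc_points.csv", index=False)
            pos = scored[scored["label"] == "positive"]
            report.update(
                {
                    "n_positive_windows": int(len(pos)),
                    "n_negative_windows": int(len(scored) - len(pos)),
                    "sensitivity_binary": float(pos["binary_hit"].mean()) if len(pos) else None,
                    "auc": roc.auc,
                }
            )
    except CohwearError as exc:
        raise CohwearError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _norm_kwargs(norm: NormParams) -> dict:
    return {
        "lookback_minutes": norm.lookback_minutes,
        "outlier_z": norm.outlier_z,
        "outlier_sided": norm.outlier_sided,
        "min_stratum_minutes": norm.min_stratum_minutes,
        "stratification": norm.stratification,
    }
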