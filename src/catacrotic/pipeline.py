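"""End-to-end orchestration: denoise -> detect -> normalize -> features
-> window summaries -> study statistics.

``run_subject`` processes one record into per-beat features and a window
summary; ``run_study`` applies it to every subject with per-subject
failure isolation, assembles the long-form study frame, and runs the
statistical battery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as _features
from .cycles import normalize_cycles
from .denoise import DenoiseConfig, DenoiseReport, select_and_denoise
from .fiducials import FiducialSet, detect_fiducials
from .stats import analyze_study
from .synthetic import PPGRecord

__all__ = ["PipelineConfig", "SubjectResult", "StageError",
           "run_subject", "run_study", "build_study_frame"]

logger = logging.getLogger("catacrotic")


class StageError(RuntimeError):
    """Failure of one pipeline stage for one subject."""

    def __init__(self, stage: str, subject: str, message: str):
        super().__init__(f"[{stage}] subject {subject}: {message}")
        self.stage = stage
        self.subject = subject


@dataclass
class PipelineConfig:
    """Processing configuration shared by all subjects.

    Analysis windows are half-open ``[start, end)`` offsets from the
    stimulus in seconds; the +-10 s band around the stimulus is outside
    both windows by construction.
    """

    fs: float = 100.0
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    detection_window_s: float = 0.6
    pre_window: tuple[float, float] = (-70.0, -10.0)
    post_window: tuple[float, float] = (10.0, 70.0)
    discard_band_s: float = 10.0
    use_clean_reference: bool = True  # rank threshold combos when clean is known

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        pre, post = self.pre_window, self.post_window
        if not (pre[0] < pre[1] <= -self.discard_band_s):
            raise ValueError("pre_window must be ordered and end at or before the discard band")
        if not (self.discard_band_s <= post[0] < post[1]):
            raise ValueError("post_window must be ordered and start at or after the discard band")


@dataclass
class SubjectResult:
    """Per-subject pipeline outputs."""

    subject_id: str
    ce: float
    summary: pd.DataFrame  # parameter -> pre_value, post_value
    beats: pd.DataFrame  # per-beat feature table
    fiducials: FiducialSet
    denoise_report: DenoiseReport | None
    n_cycles_dropped: int
    denoised: np.ndarray | None = None


def run_subject(record: PPGRecord, config: PipelineConfig | None = None,
                keep_signal: bool = False) -> SubjectResult:
    """Run the full per-subject chain on one record."""
    config = config or PipelineConfig()
    sid = record.subject_id
    ts = record.stimulus_time
    span_lo, span_hi = ts + config.pre_window[0], ts + config.post_window[1]
    if span_lo < 0 or span_hi > record.duration:
        raise StageError(
            "windows", sid,
            f"record [0, {record.duration:.1f}] s does not span the analysis "
            f"windows [{span_lo:.1f}, {span_hi:.1f}] s around the stimulus",
        )

    try:
        ref = record.clean if config.use_clean_reference else None
        denoised, report = select_and_denoise(record.signal, ref, config.denoise)
    except Exception as exc:  # noqa: BLE001
        raise StageError("denoise", sid, str(exc)) from exc

    try:
        fid = detect_fiducials(denoised, record.fs, config.detection_window_s)
        if fid.trough_indices.size < 2:
            raise ValueError("fewer than two troughs detected")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("detect", sid, str(exc)) from exc

    try:
        cycles, dropped = normalize_cycles(denoised, fid)
        beats = _features.beat_features(cycles, record.fs)
        summary = _features.summarize_beats(
            beats, ts, config.pre_window, config.post_window)
    except Exception as exc:  # noqa: BLE001
        raise StageError("features", sid, str(exc)) from exc

    logger.info(
        "subject %s: %d peaks, %d cycles (%d dropped), chosen combo %s",
        sid, fid.peak_indices.size, len(beats), dropped,
        report.chosen if report else None,
    )
    return SubjectResult(
        subject_id=sid, ce=record.ce, summary=summary, beats=beats,
        fiducials=fid, denoise_report=report, n_cycles_dropped=dropped,
        denoised=denoised if keep_signal else None,
    )


def build_study_frame(results: list[SubjectResult]) -> pd.DataFrame:
    """Long-form study frame: one row per subject and parameter."""
    rows = []
    for res in results:
        for par, row in res.summary.iterrows():
            rows.append({
                "subject": res.subject_id, "ce": res.ce, "parameter": par,
                "pre_value": row["pre_value"], "post_value": row["post_value"],
            })
    return pd.DataFrame(rows)


def run_study(records: list[PPGRecord], config: PipelineConfig | None = None) -> dict:
    """Process every subject and run the statistical battery.

    A failing subject is excluded and logged rather than aborting the
    study.  Returns a JSON-serializable report with the per-subject frame
    under ``"frame"`` and the statistics under ``"analysis"``.
    """
    config = config or PipelineConfig()
    results: list[SubjectResult] = []
    failures: list[dict] = []
    for record in records:
        try:
            results.append(run_subject(record, config))
        except StageError as exc:
            logger.warning("excluding subject: %s", exc)
            failures.append({"subject": exc.subject, "stage": exc.stage,
                             "error": str(exc)})
    if not results:
        raise RuntimeError("every subject failed; nothing to analyze")

    frame = build_study_frame(results)
    n_groups = frame["ce"].nunique()
    if n_groups >= 2:
        analysis = analyze_study(frame)
    else:
        analysis = {"notices": ["single group: comparative analysis skipped"]}

    return {
        "n_subjects": len(results),
        "n_excluded": len(failures),
        "failures": failures,
        "frame": frame.to_dict(orient="records"),
        "analysis": analysis,
        "config": {
            "fs": config.fs,
            "wavelet": config.denoise.wavelet,
            "levels": config.denoise.levels,
            "rule": config.denoise.rule,
            "mode": config.denoise.mode,
            "detection_window_s": config.detection_window_s,
            "pre_window": list(config.pre_window),
            "post_window": list(config.post_window),
        },
    }
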