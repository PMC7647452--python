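"""CSV/JSON readers and writers for records, fiducials and results.

A record is a two-column CSV (``time_s,amplitude``) plus a sidecar JSON
carrying the sampling rate, stimulus time, subject id, concentration and
seed.  Ground truth, fiducials, feature tables and reports use the plain
formats documented on each function.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .fiducials import FiducialSet
from .synthetic import GroundTruth, PPGRecord

__all__ = [
    "write_record",
    "read_record",
    "write_ground_truth",
    "write_fiducials",
    "read_fiducials",
    "write_report",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_record(record: PPGRecord, path) -> Path:
    """Write ``time_s,amplitude`` CSV plus the ``.meta.json`` sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": record.times, "amplitude": record.signal})
    df.to_csv(path, index=False, float_format="%.6f")
    meta = {
        "fs": record.fs,
        "stimulus_time_s": record.stimulus_time,
        "subject_id": record.subject_id,
        "ce_ng_ml": record.ce,
        "seed": record.seed,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_record(path) -> PPGRecord:
    """Read a record CSV; metadata comes from the sidecar when present,
    otherwise the sampling rate is inferred from the time column."""
    path = Path(path)
    df = pd.read_csv(path)
    if not {"time_s", "amplitude"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s,amplitude")
    t = df["time_s"].to_numpy(dtype=float)
    meta_path = _sidecar(path)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        meta = {}
    fs = float(meta.get("fs") or round(1.0 / float(np.median(np.diff(t)))))
    return PPGRecord(
        signal=df["amplitude"].to_numpy(dtype=float),
        fs=fs,
        stimulus_time=float(meta.get("stimulus_time_s", math.nan)),
        subject_id=str(meta.get("subject_id", path.stem)),
        ce=float(meta.get("ce_ng_ml", 0.0)),
        seed=meta.get("seed"),
    )


def write_ground_truth(truth: GroundTruth, path) -> Path:
    """JSON with trough/peak times and the per-beat true parameter table."""
    path = Path(path)
    payload = {
        "fs": truth.fs,
        "peak_times_s": truth.peak_times.tolist(),
        "trough_times_s": truth.trough_times.tolist(),
        "features": truth.features.to_dict(orient="records"),
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def write_fiducials(fid: FiducialSet, path) -> Path:
    """CSV ``type,index,time_s`` sorted by sample index."""
    path = Path(path)
    rows = [("peak", int(i), i / fid.fs) for i in fid.peak_indices]
    rows += [("trough", int(i), i / fid.fs) for i in fid.trough_indices]
    rows.sort(key=lambda r: r[1])
    pd.DataFrame(rows, columns=["type", "index", "time_s"]).to_csv(path, index=False)
    return path


def read_fiducials(path, fs: float) -> FiducialSet:
    df = pd.read_csv(path)
    return FiducialSet(
        df.loc[df["type"] == "peak", "index"].to_numpy(dtype=np.int64),
        df.loc[df["type"] == "trough", "index"].to_numpy(dtype=np.int64),
        fs,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if math.isfinite(f) else repr(f)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def write_report(report: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(report), indent=1))
    return path
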