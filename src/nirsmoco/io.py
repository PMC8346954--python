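"""File formats: CSV time series, multipage TIFF thermal video, ROI JSON,
optional SNIRF import, and provenance records.

CSV is the canonical interchange format (8 channels x 3000 samples is
trivially human-auditable): header ``time,ch1..chN`` for fNIRS, header
``time,displacement_px,gamma,interpolated`` for motion traces, seconds and
'.' decimals throughout.  Thermal video travels as multipage TIFF with one
32-bit float frame (degrees Celsius) per page.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import FnirsRecording, MotionTrace, RoiSpec, ThermalVideo

__all__ = [
    "read_timeseries_csv",
    "write_fnirs_csv",
    "write_motion_csv",
    "read_thermal_tiff",
    "write_thermal_tiff",
    "read_roi_json",
    "write_roi_json",
    "import_snirf",
    "write_provenance",
]

_MAX_JITTER = 0.1  # fraction of the sampling period


def _infer_fs(time: np.ndarray, path: str) -> float:
    dt = np.diff(time)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 2  # 1-based data line of the offender
        raise ValueError(f"{path}: non-monotone or duplicated timestamp at data row {bad}")
    period = float(np.median(dt))
    if np.max(np.abs(dt - period)) > _MAX_JITTER * period:
        raise ValueError(f"{path}: sampling jitter exceeds {_MAX_JITTER:.0%} of the period")
    return 1.0 / period


def read_timeseries_csv(path: str | Path) -> FnirsRecording | MotionTrace:
    """Read a time-series CSV; dispatches on the header.

    A ``displacement_px`` column yields a :class:`MotionTrace`; otherwise
    every non-time column becomes an fNIRS channel.  Sampling uniformity is
    verified (max jitter < 10% of the period) and ``fs`` inferred from the
    median interval.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged rows / missing values")
    if df.columns[0] != "time":
        raise ValueError(f"{path}: first column must be 'time'")
    fs = _infer_fs(df["time"].to_numpy(dtype=float), str(path))
    if "displacement_px" in df.columns:
        mask = (
            df["interpolated"].to_numpy().astype(bool)
            if "interpolated" in df.columns
            else None
        )
        return MotionTrace(
            values=df["displacement_px"].to_numpy(dtype=float), fs=fs, interpolated_mask=mask
        )
    channels = [c for c in df.columns if c != "time"]
    return FnirsRecording(
        data=df[channels].to_numpy(dtype=float).T, fs=fs, channel_labels=channels
    )


def write_fnirs_csv(path: str | Path, recording: FnirsRecording) -> None:
    df = pd.DataFrame({"time": recording.times})
    for i, label in enumerate(recording.channel_labels):
        df[label] = recording.data[i]
    df.to_csv(path, index=False, float_format="%.17g")


def write_motion_csv(path: str | Path, trace: MotionTrace, gamma: np.ndarray | None = None) -> None:
    n = len(trace.values)
    df = pd.DataFrame(
        {
            "time": np.arange(n) / trace.fs,
            "displacement_px": trace.values,
            "gamma": gamma if gamma is not None else np.ones(n),
            "interpolated": trace.interpolated_mask.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_thermal_tiff(path: str | Path, fs: float = 10.0) -> ThermalVideo:
    """Multipage TIFF -> ThermalVideo; one single-channel float page per frame."""
    frames = tifffile.imread(str(path))
    if frames.size == 0:
        raise ValueError(f"{path}: empty TIFF")
    frames = np.atleast_3d(frames)
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected single-channel pages")
    return ThermalVideo(frames=np.asarray(frames, dtype=float), fs=fs)


def write_thermal_tiff(path: str | Path, video: ThermalVideo) -> None:
    tifffile.imwrite(str(path), video.frames.astype(np.float32), photometric="minisblack")


def read_roi_json(path: str | Path) -> RoiSpec:
    spec = json.loads(Path(path).read_text())
    m = spec["mroi"]
    srois = tuple(
        (s["center"][0], s["center"][1], s["semi_axes"][0], s["semi_axes"][1])
        for s in spec.get("srois", [])
    )
    return RoiSpec(
        mroi_center=tuple(m["center"]),
        mroi_height=int(m["height"]),
        mroi_width=int(m["width"]),
        srois=srois,
        gamma_th=float(spec.get("gamma_th", 0.995)),
        pyramid_level=int(spec.get("pyramid_level", 1)),
    )


def write_roi_json(path: str | Path, roi: RoiSpec) -> None:
    spec = {
        "mroi": {
            "center": list(roi.mroi_center),
            "height": roi.mroi_height,
            "width": roi.mroi_width,
        },
        "srois": [
            {"center": [s[0], s[1]], "semi_axes": [s[2], s[3]]} for s in roi.srois
        ],
        "gamma_th": roi.gamma_th,
        "pyramid_level": roi.pyramid_level,
    }
    Path(path).write_text(json.dumps(spec, indent=2))


def import_snirf(path: str | Path) -> FnirsRecording:
    """Read a minimal SNIRF (HDF5) file: /nirs/data1/{dataTimeSeries,time}
    plus measurementList entries for the channel -> detector map."""
    import h5py

    with h5py.File(path, "r") as f:
        if "nirs/data1" not in f:
            raise ValueError("SNIRF file missing mandatory group 'nirs/data1'")
        g = f["nirs/data1"]
        for name in ("dataTimeSeries", "time"):
            if name not in g:
                raise ValueError(f"SNIRF file missing mandatory dataset 'nirs/data1/{name}'")
        data = np.asarray(g["dataTimeSeries"])  # time x channels per SNIRF
        time = np.asarray(g["time"]).ravel()
        if len(time) == 2:  # SNIRF allows [start, dt]
            fs = 1.0 / float(time[1])
        else:
            fs = _infer_fs(time, str(path))
        det_map: dict[int, int] = {}
        labels = []
        ml_names = sorted(
            (k for k in g.keys() if k.startswith("measurementList")),
            key=lambda k: int(k.replace("measurementList", "") or 0),
        )
        for i, name in enumerate(ml_names):
            ml = g[name]
            det = int(np.asarray(ml["detectorIndex"]).ravel()[0]) if "detectorIndex" in ml else 0
            src = int(np.asarray(ml["sourceIndex"]).ravel()[0]) if "sourceIndex" in ml else 0
            det_map[i] = det
            labels.append(f"S{src}D{det}")
        rec = FnirsRecording(data=data.T, fs=fs)
        if det_map:
            if len(det_map) != rec.n_channels:
                raise ValueError("measurementList length does not match channel count")
            rec.channel_to_detector = det_map
            rec.channel_labels = labels
        return rec


def write_provenance(path: str | Path, config: dict) -> None:
    """Machine-readable run record: the config, its hash, and versions."""
    import nirsmoco

    blob = json.dumps(config, sort_keys=True, default=str)
    record = {
        "config": json.loads(blob),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "versions": {
            "nirsmoco": nirsmoco.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(record, indent=2))
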