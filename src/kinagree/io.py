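"""CSV import/export mirroring the device's cloud export and the reference system's traces.

Device export: ``t, qw, qx, qy, qz, ax, ay, az, gx, gy, gz`` at 30 Hz.
Reference export: ``t, angle_deg`` plus an optional ``marker_y`` column
carrying the synchronization-artifact trajectory.

Both writers use fixed 6-decimal formatting so identical in-memory data
produce byte-identical files; both readers validate schema, timestamp
monotonicity, finiteness and quaternion norms, reporting offending rows
by line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .traces import AngleTrace, QuatStream

__all__ = [
    "IMU_COLUMNS",
    "read_imu_csv",
    "write_imu_csv",
    "read_angle_csv",
    "write_angle_csv",
]

IMU_COLUMNS = ["t", "qw", "qx", "qy", "qz", "ax", "ay", "az", "gx", "gy", "gz"]
_FLOAT_FMT = "%.6f"
_QUAT_TOL = 1e-3  # export rounding leaves norms this close to 1


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def _check_finite(df: pd.DataFrame, cols: list[str], path) -> None:
    block = df[cols].to_numpy(dtype=float)
    bad = ~np.isfinite(block)
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: non-finite value at line {row + 2}")


def _infer_rate(t: np.ndarray, path) -> float:
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) if t.size >= 2 else 0
        raise ValueError(f"{path}: timestamps not strictly increasing at line {row + 3}")
    if not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-6):
        raise ValueError(f"{path}: non-uniform sampling interval")
    return 1.0 / float(np.mean(dt))


def read_imu_csv(path) -> QuatStream:
    """Parse a device export into a :class:`QuatStream`."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, IMU_COLUMNS, path)
    _check_finite(df, IMU_COLUMNS, path)
    t = df["t"].to_numpy(dtype=float)
    rate = _infer_rate(t, path)
    quat = df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
    norms = np.linalg.norm(quat, axis=1)
    bad = np.abs(norms - 1.0) > _QUAT_TOL
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f"{path}: non-unit quaternion at line {i + 2} (|q| = {norms[i]:.4f})"
        )
    quat /= norms[:, None]
    return QuatStream(
        quat=quat,
        acc=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
        rate=rate,
        t0=float(t[0]),
    )


def write_imu_csv(stream: QuatStream, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([stream.times, stream.quat, stream.acc, stream.gyro]),
        columns=IMU_COLUMNS,
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_angle_csv(path, system: str = "MoCap", task_name: str = "") -> AngleTrace:
    """Parse a reference angle export (``t, angle_deg[, marker_y]``)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["t", "angle_deg"], path)
    cols = ["t", "angle_deg"] + (["marker_y"] if "marker_y" in df.columns else [])
    _check_finite(df, cols, path)
    t = df["t"].to_numpy(dtype=float)
    rate = _infer_rate(t, path)
    marker = df["marker_y"].to_numpy(dtype=float) if "marker_y" in df.columns else None
    return AngleTrace(
        values=df["angle_deg"].to_numpy(dtype=float),
        rate=rate,
        t0=float(t[0]),
        system=system,
        task_name=task_name,
        marker=marker,
    )


def write_angle_csv(trace: AngleTrace, path) -> Path:
    path = Path(path)
    data = {"t": trace.times, "angle_deg": trace.values}
    if trace.marker is not None:
        data["marker_y"] = trace.marker
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path
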