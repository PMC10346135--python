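"""Shared in-memory containers for angle traces and raw IMU streams.

An :class:`AngleTrace` is a uniformly sampled scalar body-segment angle
series in degrees; a :class:`QuatStream` mirrors the device's CSV export:
30 Hz unit quaternions plus raw tri-axial accelerometer and gyroscope
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["AngleTrace", "QuatStream"]

_QUAT_NORM_TOL = 1e-6


@dataclass
class AngleTrace:
    """Uniformly sampled body-segment angle series (degrees).

    Parameters
    ----------
    values : array of float
        Angle samples in degrees.
    rate : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample, seconds.
    system : str
        Measurement system tag, ``"IMU"`` or ``"MoCap"``.
    task_name : str
        Motor-task label.
    marker : array or None
        Optional auxiliary marker-trajectory channel carrying the
        synchronization artifact (MoCap exports only), same sampling.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    system: str = "IMU"
    task_name: str = ""
    marker: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("AngleTrace values must be one-dimensional")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("AngleTrace values must be finite")
        if self.marker is not None:
            self.marker = np.asarray(self.marker, dtype=float)
            if self.marker.shape != self.values.shape:
                raise ValueError("marker channel must match values in length")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.values.size) / self.rate

    @property
    def duration(self) -> float:
        return (self.values.size - 1) / self.rate if self.values.size else 0.0

    def with_values(self, values: np.ndarray, **kw) -> "AngleTrace":
        """Copy of this trace with new samples (and optional field overrides)."""
        return replace(self, values=np.asarray(values, dtype=float), **kw)


@dataclass
class QuatStream:
    """30 Hz device record: orientation quaternions plus raw inertial channels.

    ``quat`` rows are scalar-first unit quaternions ``(w, x, y, z)``; ``acc``
    and ``gyro`` are tri-axial raw samples (m/s^2 and deg/s). The stream's
    time axis is the device's own clock, which may be offset from the
    reference system's clock by an unknown lag.
    """

    quat: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    rate: float = 30.0
    t0: float = 0.0
    task_name: str = ""

    def __post_init__(self) -> None:
        self.quat = np.asarray(self.quat, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.quat.ndim != 2 or self.quat.shape[1] != 4:
            raise ValueError("quat must be an (n, 4) array of (w, x, y, z) rows")
        for name, arr in (("acc", self.acc), ("gyro", self.gyro)):
            if arr.shape != (self.quat.shape[0], 3):
                raise ValueError(f"{name} must be an (n, 3) array matching quat")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        norms = np.linalg.norm(self.quat, axis=1)
        bad = np.abs(norms - 1.0) > _QUAT_NORM_TOL
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"non-unit quaternion at sample {i}: |q| = {norms[i]:.6f}"
            )

    def __len__(self) -> int:
        return self.quat.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate
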