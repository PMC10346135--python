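"""One-session processing chain: orientation -> synchronization -> segmentation -> ROM.

:func:`process_session` runs a single paired session (synthetic or loaded
from CSV exports) through the same stages the validation study applies:
extract the device's flexion-angle trace from the quaternion stream,
downsample the reference trace to the IMU rate, estimate the clock lag
from the stomp artifact, align and remove the constant offset, then
segment each system's trace into repetitions and compute the
working-phase ROM per repetition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .orientation import segment_angle_trace
from .segment import DEFAULT_N_POINTS, DEFAULT_TAU, ROMEstimate, rom_estimate_for_trace
from .sync import (
    SyncResult,
    align_and_remove_offset,
    downsample_to_imu_rate,
    estimate_session_lag,
)
from .synth import SyntheticSession
from .traces import AngleTrace, QuatStream

__all__ = ["PipelineParams", "SessionResult", "process_session", "process_streams"]


@dataclass(frozen=True)
class PipelineParams:
    """Tunable processing parameters, defaults as used throughout the study."""

    tau: float = DEFAULT_TAU  # working-phase threshold on the normalized cycle
    fc: float = 5.0  # Butterworth cutoff, Hz
    filter_order: int = 3
    n_points: int = DEFAULT_N_POINTS  # cycle resample length
    prominence_frac: float = 0.25  # repetition-peak prominence vs global excursion
    rest_window: float = 2.0  # seconds of rest used for offset / baseline
    max_lag_seconds: float = 2.0
    plane_axis: str = "z"  # flexion/extension component of the ZYX sequence


@dataclass(frozen=True)
class SessionResult:
    rom_imu: ROMEstimate
    rom_mocap: ROMEstimate
    sync: SyncResult


def process_streams(
    imu_stream: QuatStream,
    mocap_trace: AngleTrace,
    expected_n: int | None = None,
    params: PipelineParams = PipelineParams(),
    side: str = "",
) -> SessionResult:
    """Run the full chain on raw paired streams.

    ``mocap_trace`` must carry its marker channel (the artifact bearer);
    the IMU's x-axis acceleration is the device-side artifact channel.
    """
    if mocap_trace.marker is None:
        raise ValueError("reference trace must include the sync-marker channel")
    imu_angle = segment_angle_trace(imu_stream, params.plane_axis)
    mocap30 = downsample_to_imu_rate(mocap_trace, imu_rate=imu_stream.rate)
    lag = estimate_session_lag(
        imu_stream.acc[:, 0],
        mocap30.marker,
        rate=imu_stream.rate,
        fc=params.fc,
        order=params.filter_order,
        max_lag_seconds=params.max_lag_seconds,
    )
    sync = align_and_remove_offset(
        imu_angle, mocap30, lag, rest_window=params.rest_window
    )
    kw = dict(
        expected_n=expected_n,
        tau=params.tau,
        rest_window=params.rest_window,
        prominence_frac=params.prominence_frac,
        n_points=params.n_points,
        side=side,
    )
    rom_imu = rom_estimate_for_trace(sync.imu_aligned, **kw)
    rom_mocap = rom_estimate_for_trace(sync.mocap_aligned, **kw)
    return SessionResult(rom_imu=rom_imu, rom_mocap=rom_mocap, sync=sync)


def process_session(
    session: SyntheticSession,
    params: PipelineParams = PipelineParams(),
    side: str = "",
) -> SessionResult:
    """Run the full chain on one synthetic session (expected repetition count
    taken from the session's own template)."""
    return process_streams(
        session.imu_stream,
        session.mocap_trace,
        expected_n=session.config.template.n_repetitions,
        params=params,
        side=side,
    )
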