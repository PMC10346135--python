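"""Synthetic paired IMU / MoCap session generator with known ground truth.

Each session emulates one biofeedback-guided exercise bout: a lead-in rest
during which the subject stamps a foot (the shared synchronization
artifact), then ``n_repetitions`` rest-ramp-hold-return cycles about a
single motion axis. The reference stream is the segment angle sampled at
100 Hz with Gaussian noise and a constant inter-system offset; the device
stream renders the same motion as 30 Hz unit quaternions (rotation about
the sensor's flexion axis), optionally remounted by a fixed axial rotation
(sensor misplacement) and shifted by an unknown clock lag.

Because every corruption is injected with a known value, each downstream
stage (synchronization, segmentation, ROM, agreement) can be tested against
exact ground truth without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .reference import BILATERAL_TASKS, REFERENCE_ROM, TASKS
from .traces import AngleTrace, QuatStream

__all__ = [
    "TaskTemplate",
    "SimConfig",
    "SessionTruth",
    "SyntheticSession",
    "make_template",
    "ground_truth_angle",
    "generate_session",
    "apply_misplacement",
    "misplacement_angle_from_shift",
    "GRAVITY",
]

GRAVITY = 9.81  # m/s^2, resting accelerometer baseline on the longitudinal axis

#: Axial misplacement equivalent to the protocol's 10 %-of-thigh-diameter
#: circumferential shift: arc length 0.1*d over radius d/2 -> 0.2 rad.
DEFAULT_MISPLACEMENT_DEG = float(np.degrees(0.2))  # ~11.46 deg


def misplacement_angle_from_shift(shift_fraction: float = 0.1) -> float:
    """Axial rotation (degrees) for a circumferential shift of ``shift_fraction``
    of the segment diameter: theta = (f*d) / (d/2) radians."""
    return float(np.degrees(2.0 * shift_fraction))


@dataclass(frozen=True)
class TaskTemplate:
    """Rest-ramp-hold-return repetition profile for one motor task.

    The hold phase is long relative to the ramps because the device's
    audio-video biofeedback instructs the subject to reach and *hold* the
    target excursion; the working-phase ROM statistic averages the plateau,
    so the plateau dominates each cycle.
    """

    task_name: str
    target_rom: float  # degrees, plateau amplitude
    n_repetitions: int = 10
    rest_duration: float = 1.7  # seconds of rest closing each cycle
    ramp_duration: float = 0.3  # seconds, each of the up/down ramps
    hold_duration: float = 10.0  # seconds at the plateau
    lead_in: float = 3.0  # initial rest hosting the sync artifact
    bilateral: bool = False

    def __post_init__(self) -> None:
        if self.target_rom <= 0:
            raise ValueError("target_rom must be positive")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be at least 1")
        for name in ("rest_duration", "ramp_duration", "hold_duration", "lead_in"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def cycle_duration(self) -> float:
        return 2 * self.ramp_duration + self.hold_duration + self.rest_duration

    @property
    def session_duration(self) -> float:
        return self.lead_in + self.n_repetitions * self.cycle_duration


def make_template(task_name: str, **overrides) -> TaskTemplate:
    """Template for one of the seven study tasks.

    The default ``target_rom`` is the reference cohort's MoCap ROM mean for
    that task; any field can be overridden by keyword.
    """
    if task_name not in TASKS:
        raise ValueError(
            f"unknown task {task_name!r}; valid tasks: {', '.join(TASKS)}"
        )
    defaults = dict(
        task_name=task_name,
        target_rom=REFERENCE_ROM[task_name].mocap_mean,
        bilateral=task_name in BILATERAL_TASKS,
    )
    defaults.update(overrides)
    return TaskTemplate(**defaults)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """C1 ramp: 3u^2 - 2u^3 on [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def ground_truth_angle(template: TaskTemplate, t) -> np.ndarray | float:
    """Noise-free segment angle (degrees) at time(s) ``t`` seconds.

    Zero during rest, smoothstep ramps to a plateau at ``target_rom`` held
    for ``hold_duration``, smoothstep return, repeated ``n_repetitions``
    times after the lead-in. Raises for times outside the session span.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > template.session_duration + 1e-9):
        raise ValueError(
            f"time outside session span [0, {template.session_duration:.3f}] s"
        )
    tt = t_arr - template.lead_in
    tau = np.mod(tt, template.cycle_duration)
    # times before the lead-in sit in rest; mask them out of the cycle math
    in_motion = tt >= 0
    r, h = template.ramp_duration, template.hold_duration
    up = _smoothstep(tau / r)
    down = 1.0 - _smoothstep((tau - r - h) / r)
    profile = np.where(tau < r, up, np.where(tau < r + h, 1.0, np.where(tau < 2 * r + h, down, 0.0)))
    out = template.target_rom * np.where(in_motion, profile, 0.0)
    return out if t_arr.ndim else float(out)


@dataclass(frozen=True)
class SimConfig:
    """Everything that parameterizes one synthetic paired session.

    ``lag`` is the device clock's delay relative to the reference clock: an
    event at reference time t appears at device time t + lag.
    ``inter_system_offset`` is a constant added to the reference angle
    trace. ``imu_rom_bias`` scales the device-side rendering so its plateau
    sits at ``target_rom + imu_rom_bias`` — the knob that lets a cohort
    simulation reproduce a prescribed between-system ROM discrepancy.
    """

    template: TaskTemplate
    imu_rate: float = 30.0
    mocap_rate: float = 100.0
    mocap_noise_sd: float = 0.5  # degrees
    imu_noise_sd: float = 1.0  # degrees
    inter_system_offset: float = 0.0  # degrees added to the MoCap trace
    lag: float = 0.0  # seconds, device clock minus reference clock
    stomp_time: float = 1.0  # seconds into the lead-in (reference clock)
    stomp_amplitude: float = 20.0  # artifact spike height (accel units)
    accel_noise_sd: float = 0.2  # m/s^2
    misplacement_angle: float = 0.0  # degrees of axial sensor rotation
    imu_rom_bias: float = 0.0  # degrees
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.imu_rate <= 0 or self.mocap_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if self.mocap_noise_sd < 0 or self.imu_noise_sd < 0 or self.accel_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if abs(self.misplacement_angle) >= 90.0:
            raise ValueError("misplacement angle must satisfy |theta| < 90 deg")
        lead = self.template.lead_in
        if not (self.stomp_time + 0.3 < lead):
            raise ValueError("stomp artifact must fall inside the lead-in rest")
        if self.lag < -(self.stomp_time - 0.3) or self.lag > 2.0:
            raise ValueError(
                "lag must lie within [-(stomp_time - 0.3), 2.0] s so the "
                "artifact stays recordable in both streams"
            )


@dataclass(frozen=True)
class SessionTruth:
    """Injected ground truth a downstream stage should recover."""

    rom_per_rep_mocap: np.ndarray  # degrees, one per repetition
    rom_per_rep_imu: np.ndarray
    lag_seconds: float
    lag_samples: int  # at the IMU rate
    offset: float  # degrees added to the MoCap trace
    misplacement_angle: float


@dataclass(frozen=True)
class SyntheticSession:
    imu_stream: QuatStream
    mocap_trace: AngleTrace
    truth: SessionTruth
    config: SimConfig


def _stomp_pulses(t: np.ndarray, t0: float, amplitude: float) -> np.ndarray:
    """Three Gaussian spikes (sigma 40 ms, 120 ms apart) starting at ``t0``."""
    out = np.zeros_like(t)
    for k, gain in enumerate((1.0, 0.85, 0.7)):
        c = t0 + 0.12 * k
        out += amplitude * gain * np.exp(-0.5 * ((t - c) / 0.04) ** 2)
    return out


def generate_session(config: SimConfig) -> SyntheticSession:
    """Generate one paired session; byte-for-byte reproducible under ``rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    tpl = config.template
    span = tpl.session_duration

    # --- reference (MoCap) stream: angle + marker channel at 100 Hz -------
    n_mc = int(round(span * config.mocap_rate)) + 1
    t_mc = np.arange(n_mc) / config.mocap_rate
    truth_mc = ground_truth_angle(tpl, t_mc)
    mocap_vals = (
        truth_mc
        + config.inter_system_offset
        + rng.normal(0.0, config.mocap_noise_sd, n_mc)
    )
    marker = _stomp_pulses(t_mc, config.stomp_time, config.stomp_amplitude)
    marker += rng.normal(0.0, 0.01 * config.stomp_amplitude + 1e-3, n_mc)
    mocap = AngleTrace(
        values=mocap_vals,
        rate=config.mocap_rate,
        system="MoCap",
        task_name=tpl.task_name,
        marker=marker,
    )

    # --- device (IMU) stream at 30 Hz on its own (lagged) clock ----------
    n_imu = int(round((span + max(config.lag, 0.0)) * config.imu_rate)) + 1
    t_imu = np.arange(n_imu) / config.imu_rate  # device clock
    t_phys = np.clip(t_imu - config.lag, 0.0, span)  # reference clock
    scale = (tpl.target_rom + config.imu_rom_bias) / tpl.target_rom
    angle_imu = scale * ground_truth_angle(tpl, t_phys)
    angle_imu = angle_imu + rng.normal(0.0, config.imu_noise_sd, n_imu)

    # rotation about the sensor's flexion (Z) axis, scalar-first quaternions
    rot = Rotation.from_euler("z", angle_imu[:, None], degrees=True)
    quat = np.roll(rot.as_quat(), 1, axis=1)  # xyzw -> wxyz

    acc = rng.normal(0.0, config.accel_noise_sd, (n_imu, 3))
    acc[:, 0] += _stomp_pulses(t_imu, config.stomp_time + config.lag, config.stomp_amplitude)
    acc[:, 2] += GRAVITY
    gyro = rng.normal(0.0, 0.5, (n_imu, 3))
    gyro[:, 2] += np.gradient(angle_imu, 1.0 / config.imu_rate)

    stream = QuatStream(
        quat=quat, acc=acc, gyro=gyro, rate=config.imu_rate, task_name=tpl.task_name
    )
    if config.misplacement_angle != 0.0:
        stream = apply_misplacement(stream, config.misplacement_angle)

    truth = SessionTruth(
        rom_per_rep_mocap=np.full(tpl.n_repetitions, tpl.target_rom),
        rom_per_rep_imu=np.full(tpl.n_repetitions, tpl.target_rom + config.imu_rom_bias),
        lag_seconds=config.lag,
        lag_samples=int(round(config.lag * config.imu_rate)),
        offset=config.inter_system_offset,
        misplacement_angle=config.misplacement_angle,
    )
    return SyntheticSession(imu_stream=stream, mocap_trace=mocap, truth=truth, config=config)


def apply_misplacement(stream: QuatStream, misplacement_angle: float) -> QuatStream:
    """Remount the sensor rotated by ``misplacement_angle`` about its longitudinal axis.

    A circumferential shift of the thigh-worn sensor rotates the sensor
    frame about the segment's longitudinal axis (the internal/external, Y,
    axis of the device's ZYX convention). The motion the sensor reports is
    then the segment rotation conjugated into the displaced frame,
    ``q' = r^-1 q r`` with ``r`` the fixed axial rotation: for single-plane
    motion of amplitude A this attenuates the extracted in-plane angle to
    approximately ``A * cos(theta)``, symmetrically in +/-theta.
    """
    if abs(misplacement_angle) >= 90.0:
        raise ValueError("misplacement angle must satisfy |theta| < 90 deg")
    if misplacement_angle == 0.0:
        return stream
    r = Rotation.from_euler("y", misplacement_angle, degrees=True)
    q = Rotation.from_quat(np.roll(stream.quat, -1, axis=1))  # wxyz -> xyzw
    q_new = r.inv() * q * r
    quat = np.roll(q_new.as_quat(), 1, axis=1)
    return replace(stream, quat=quat)
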