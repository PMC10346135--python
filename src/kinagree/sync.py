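"""Temporal alignment of the 100 Hz reference trace and the 30 Hz IMU stream.

The two systems share no hardware trigger; alignment uses the deliberate
foot-stamp artifact visible in both streams (marker trajectory on the
reference side, x-axis acceleration on the device side). The reference
channel is anti-alias downsampled to the IMU rate, both artifact channels
are passed through the same causal low-pass Butterworth filter — identical
filtering on both sides so the filter's group delay cancels out of the lag
estimate — the spike windows are isolated, and the integer-sample lag
maximizing the normalized cross-correlation is taken. The constant
inter-system offset is then estimated from the rest-phase means and
removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .traces import AngleTrace

__all__ = [
    "SyncResult",
    "ArtifactNotFoundError",
    "downsample_to_imu_rate",
    "lowpass_butterworth",
    "isolate_artifact_window",
    "xcorr_lag",
    "align_and_remove_offset",
    "estimate_session_lag",
]

IMU_RATE = 30.0


class ArtifactNotFoundError(RuntimeError):
    """No spike stands out of the signal; select the window manually."""


@dataclass(frozen=True)
class SyncResult:
    """Outcome of aligning one session's two angle traces."""

    lag_samples: int  # at the IMU rate; positive = IMU stream delayed
    lag_seconds: float
    offset: float  # degrees, IMU rest mean minus MoCap rest mean
    imu_aligned: AngleTrace
    mocap_aligned: AngleTrace

    def __post_init__(self) -> None:
        if len(self.imu_aligned) != len(self.mocap_aligned):
            raise ValueError("aligned traces must have equal length")


def downsample_to_imu_rate(trace: AngleTrace, imu_rate: float = IMU_RATE) -> AngleTrace:
    """Anti-alias resample a 100 Hz reference trace to the IMU rate (30 Hz).

    An explicit linear-phase FIR anti-alias filter (cutoff 80 % of the new
    Nyquist, zero group delay) precedes polyphase rational resampling
    (factor 3/10), so band-limited content is preserved, content above the
    new Nyquist is suppressed, and no timing shift is introduced. The
    marker channel, when present, is resampled identically.
    """
    frac = Fraction(imu_rate / trace.rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    if up >= down:
        raise ValueError(
            f"expected a higher-rate reference trace, got {trace.rate} Hz -> {imu_rate} Hz"
        )
    numtaps = 2 * int(trace.rate) + 1  # ~2 s of taps, odd for zero delay
    h = sps.firwin(numtaps, 0.8 * imu_rate / 2.0, fs=trace.rate)

    def _resample(x: np.ndarray) -> np.ndarray:
        return sps.resample_poly(np.convolve(x, h, mode="same"), up, down)

    values = _resample(trace.values)
    marker = None
    if trace.marker is not None:
        marker = _resample(trace.marker)
    return AngleTrace(
        values=values,
        rate=imu_rate,
        t0=trace.t0,
        system=trace.system,
        task_name=trace.task_name,
        marker=marker,
    )


def lowpass_butterworth(
    x: np.ndarray, fs: float, fc: float = 5.0, order: int = 3
) -> np.ndarray:
    """Causal single-pass low-pass Butterworth filter (default 3rd order, 5 Hz)."""
    if fc <= 0 or fc >= fs / 2:
        raise ValueError(f"cutoff must satisfy 0 < fc < fs/2, got fc={fc}, fs={fs}")
    sos = sps.butter(order, fc, btype="low", fs=fs, output="sos")
    return sps.sosfilt(sos, np.asarray(x, dtype=float))


def isolate_artifact_window(
    x: np.ndarray,
    rate: float,
    pad: float = 0.3,
    min_snr: float = 6.0,
    cluster_gap: float = 0.5,
) -> tuple[int, int]:
    """Locate the sample window bracketing the largest spike cluster.

    Spikes are excursions of ``|x - median|`` exceeding ``min_snr`` robust
    SDs (median absolute deviation scaled to Gaussian sigma). Peaks closer
    than ``cluster_gap`` seconds are merged into one cluster; the cluster
    containing the tallest peak, padded by ``pad`` seconds each side, is
    returned as a half-open index range.
    """
    x = np.asarray(x, dtype=float)
    dev = np.abs(x - np.median(x))
    mad = np.median(dev)
    sigma = 1.4826 * mad if mad > 0 else 0.0
    floor = max(min_snr * sigma, 1e-12)
    if dev.max() <= floor:
        raise ArtifactNotFoundError(
            "no spike exceeds the prominence threshold; pass an explicit window"
        )
    peaks, _ = sps.find_peaks(dev, height=max(floor, 0.5 * dev.max()))
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(dev))])
    # cluster peaks and keep the cluster holding the global maximum
    gap = max(1, int(round(cluster_gap * rate)))
    splits = np.where(np.diff(peaks) > gap)[0]
    clusters = np.split(peaks, splits + 1)
    top = int(np.argmax(dev[peaks]))
    tallest = peaks[top]
    cluster = next(c for c in clusters if tallest in c)
    pad_n = int(round(pad * rate))
    lo = max(0, int(cluster[0]) - pad_n)
    hi = min(x.size, int(cluster[-1]) + pad_n + 1)
    return lo, hi


def xcorr_lag(
    sig_a: np.ndarray, sig_b: np.ndarray, max_lag: int | None = None
) -> int:
    """Integer lag maximizing the normalized cross-correlation of two signals.

    Returns the lag ``L`` such that ``sig_b[i] ~ sig_a[i - L]`` (positive L:
    ``sig_b`` is delayed relative to ``sig_a``). Each candidate shift is
    scored by the Pearson correlation over the overlapping samples; ties are
    broken toward the smallest ``|L|``. Both signals must share a sampling
    rate and overlap by at least 3 samples at every candidate shift.
    """
    a = np.asarray(sig_a, dtype=float)
    b = np.asarray(sig_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("signals must contain at least 3 samples")
    if max_lag is None:
        max_lag = min(a.size, b.size) - 3
    max_lag = int(max_lag)
    best_lag, best_score = 0, -np.inf
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            n = min(a.size, b.size - lag)
            seg_a, seg_b = a[:n], b[lag : lag + n]
        else:
            n = min(a.size + lag, b.size)
            seg_a, seg_b = a[-lag : -lag + n], b[:n]
        if n < 3:
            continue
        sa, sb = seg_a.std(), seg_b.std()
        if sa == 0 or sb == 0:
            continue
        score = float(np.dot(seg_a - seg_a.mean(), seg_b - seg_b.mean()) / (n * sa * sb))
        if score > best_score + 1e-12 or (
            abs(score - best_score) <= 1e-12 and abs(lag) < abs(best_lag)
        ):
            best_lag, best_score = lag, score
    if not math.isfinite(best_score):
        raise ValueError("cross-correlation undefined (constant signals)")
    return best_lag


def estimate_session_lag(
    imu_accel_x: np.ndarray,
    mocap_marker_30hz: np.ndarray,
    rate: float = IMU_RATE,
    fc: float = 5.0,
    order: int = 3,
    max_lag_seconds: float = 2.0,
) -> int:
    """Lag (IMU samples) of the device stream relative to the reference stream.

    Both artifact channels are filtered with the same causal Butterworth,
    the artifact window is located on the reference channel, both channels
    are cropped to that window padded by the lag search range, and the
    normalized cross-correlation lag is returned (positive: IMU delayed).
    """
    f_imu = lowpass_butterworth(imu_accel_x, rate, fc=fc, order=order)
    f_mc = lowpass_butterworth(mocap_marker_30hz, rate, fc=fc, order=order)
    lo, hi = isolate_artifact_window(f_mc, rate)
    max_lag = int(round(max_lag_seconds * rate))
    lo_w = max(0, lo - max_lag)
    hi_w = min(min(f_imu.size, f_mc.size), hi + max_lag)
    return xcorr_lag(f_mc[lo_w:hi_w], f_imu[lo_w:hi_w], max_lag=max_lag)


def align_and_remove_offset(
    imu_trace: AngleTrace,
    mocap_trace: AngleTrace,
    lag_samples: int,
    rest_window: float = 1.0,
) -> SyncResult:
    """Crop both 30 Hz traces to a common clock and remove the constant offset.

    Positive ``lag_samples`` means the IMU stream is delayed: its first
    ``lag_samples`` samples are dropped so index i refers to the same
    physical instant in both traces. The offset is the difference of the
    rest-phase means (first ``rest_window`` seconds of the aligned traces,
    inside the lead-in rest) and is subtracted from the IMU trace.
    """
    if imu_trace.rate != mocap_trace.rate:
        raise ValueError("traces must share a sampling rate before alignment")
    imu = imu_trace.values
    mocap = mocap_trace.values
    if lag_samples >= 0:
        imu = imu[lag_samples:]
    else:
        mocap = mocap[-lag_samples:]
    n = min(imu.size, mocap.size)
    if n < 3:
        raise ValueError("no overlap between traces after shifting")
    imu, mocap = imu[:n], mocap[:n]
    n_rest = max(1, int(round(rest_window * imu_trace.rate)))
    offset = float(np.mean(imu[:n_rest]) - np.mean(mocap[:n_rest]))
    rate = imu_trace.rate
    return SyncResult(
        lag_samples=int(lag_samples),
        lag_seconds=lag_samples / rate,
        offset=offset,
        imu_aligned=imu_trace.with_values(imu - offset, t0=0.0),
        mocap_aligned=mocap_trace.with_values(mocap, t0=0.0, marker=None),
    )
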