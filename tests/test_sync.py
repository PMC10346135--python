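"""Downsampling, Butterworth filtering, artifact isolation and lag recovery."""

import numpy as np
import pytest

from kinagree import AngleTrace
from kinagree.sync import (
    ArtifactNotFoundError,
    align_and_remove_offset,
    downsample_to_imu_rate,
    estimate_session_lag,
    isolate_artifact_window,
    lowpass_butterworth,
    xcorr_lag,
)


def _sine_trace(freq, amp, rate=100.0, duration=20.0):
    t = np.arange(0.0, duration, 1.0 / rate)
    return AngleTrace(values=amp * np.sin(2 * np.pi * freq * t), rate=rate), t


# ------------------------------------------------------------ downsample


def test_downsample_preserves_dc():
    trace = AngleTrace(values=np.full(1000, 10.0), rate=100.0)
    out = downsample_to_imu_rate(trace)
    assert out.rate == 30.0
    assert out.values.size == 300
    # passband ripple of the anti-alias FIR is ~1e-4 relative
    assert np.allclose(out.values[45:-45], 10.0, atol=5e-3)  # skip edge transients


def test_downsample_preserves_in_band_sinusoid():
    trace, _ = _sine_trace(1.0, 20.0)
    out = downsample_to_imu_rate(trace)
    interior = out.values[45:-45]
    assert np.max(np.abs(interior)) == pytest.approx(20.0, rel=0.01)


def test_downsample_attenuates_above_new_nyquist():
    trace, _ = _sine_trace(14.0, 20.0)
    out = downsample_to_imu_rate(trace)
    assert np.max(np.abs(out.values[45:-45])) < 0.05 * 20.0


def test_downsample_requires_higher_rate_input():
    with pytest.raises(ValueError, match="Hz"):
        downsample_to_imu_rate(AngleTrace(values=np.zeros(100), rate=30.0))


# ------------------------------------------------------------ butterworth


def _steady_state_gain(freq, fs=2000.0, fc=5.0, order=3):
    """Amplitude of the filter's steady-state response to a unit sinusoid,
    estimated by quadrature least squares over the tail (high fs keeps the
    digital design close to the analog magnitude response)."""
    t = np.arange(0.0, 30.0, 1.0 / fs)
    y = lowpass_butterworth(np.sin(2 * np.pi * freq * t), fs, fc=fc, order=order)
    tail = slice(int(0.5 * t.size), None)
    basis = np.column_stack(
        [np.sin(2 * np.pi * freq * t[tail]), np.cos(2 * np.pi * freq * t[tail])]
    )
    coef, *_ = np.linalg.lstsq(basis, y[tail], rcond=None)
    return float(np.hypot(*coef))


def test_butterworth_dc_gain_is_unity():
    y = lowpass_butterworth(np.full(600, 7.0), 30.0)
    assert np.allclose(y[200:], 7.0, atol=1e-6)


def test_butterworth_cutoff_gain_is_minus_3db():
    assert _steady_state_gain(5.0) == pytest.approx(1.0 / np.sqrt(2.0), rel=0.01)


def test_butterworth_matches_transfer_function_oracle():
    # |H(f)| = 1 / sqrt(1 + (f/fc)^(2*order)) for a Butterworth low-pass
    for freq in (1.0, 2.5, 7.5, 15.0):
        expected = 1.0 / np.sqrt(1.0 + (freq / 5.0) ** 6)
        assert _steady_state_gain(freq) == pytest.approx(expected, rel=0.01)


def test_butterworth_rejects_cutoff_beyond_nyquist():
    with pytest.raises(ValueError, match="fc"):
        lowpass_butterworth(np.zeros(100), 30.0, fc=15.0)


# -------------------------------------------------------- artifact window


def _spiky_signal(rate=30.0, t_spikes=(1.0, 1.1, 1.2), amp=20.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 10.0, 1.0 / rate)
    x = rng.normal(0.0, noise, t.size)
    for ts in t_spikes:
        x += amp * np.exp(-0.5 * ((t - ts) / 0.04) ** 2)
    return x, t


def test_artifact_window_brackets_spike_cluster():
    x, t = _spiky_signal()
    lo, hi = isolate_artifact_window(x, 30.0, pad=0.3)
    assert t[lo] <= 1.0 - 0.2 and t[hi - 1] >= 1.2 + 0.2
    assert t[lo] > 0.0 and t[hi - 1] < 3.0  # window stays local


def test_artifact_window_robust_to_noise():
    x0, _ = _spiky_signal()
    lo0, hi0 = isolate_artifact_window(x0, 30.0)
    x1, _ = _spiky_signal(noise=2.0, seed=3)  # noise SD 10 % of spike height
    lo1, hi1 = isolate_artifact_window(x1, 30.0)
    assert abs(lo1 - lo0) <= 5 and abs(hi1 - hi0) <= 5


def test_flat_signal_raises_artifact_error():
    with pytest.raises(ArtifactNotFoundError):
        isolate_artifact_window(np.zeros(300), 30.0)


# ------------------------------------------------------------- xcorr lag


def _shifted(x, shift):
    """Delay by `shift` samples with zero padding (no wrap-around)."""
    if shift >= 0:
        return np.concatenate([np.zeros(shift), x[: x.size - shift]])
    return np.concatenate([x[-shift:], np.zeros(-shift)])


def test_xcorr_lag_zero_for_identical_signals():
    x, _ = _spiky_signal()
    assert xcorr_lag(x, x) == 0


@pytest.mark.parametrize("shift", [-60, -15, -1, 1, 15, 60])
def test_xcorr_lag_recovers_any_integer_shift_in_two_seconds(shift):
    # 60 samples at 30 Hz = 2 s, the full search range
    x, _ = _spiky_signal(t_spikes=(4.0, 4.1, 4.2))  # keep spikes clear of edges
    assert xcorr_lag(x, _shifted(x, shift), max_lag=60) == shift


def test_full_sync_stage_lag_monte_carlo_snr10():
    """The sync stage (filter both channels, isolate artifact, cross-correlate)
    recovers an injected 15-sample lag in >= 95 % of trials at spike SNR 10."""
    hits = 0
    n_trials = 100
    for seed in range(n_trials):
        rng = np.random.default_rng(seed)
        x, _ = _spiky_signal()
        mocap_like = x + rng.normal(0.0, 2.0, x.size)
        imu_like = _shifted(x, 15) + rng.normal(0.0, 2.0, x.size)
        hits += estimate_session_lag(imu_like, mocap_like) == 15
    assert hits >= 95


def test_xcorr_lag_short_windows_rejected():
    with pytest.raises(ValueError, match="3 samples"):
        xcorr_lag(np.ones(2), np.ones(2))


# --------------------------------------------------- align / offset / e2e


def _trace(values, rate=30.0, **kw):
    return AngleTrace(values=np.asarray(values, dtype=float), rate=rate, **kw)


def test_align_identity_when_nothing_to_fix():
    v = np.concatenate([np.zeros(60), np.sin(np.linspace(0, 3 * np.pi, 300))])
    res = align_and_remove_offset(_trace(v), _trace(v), lag_samples=0)
    assert res.lag_samples == 0
    assert res.offset == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(res.imu_aligned.values, v)


def test_align_removes_constant_offset():
    v = np.concatenate([np.zeros(60), 10 * np.sin(np.linspace(0, 3 * np.pi, 300))])
    res = align_and_remove_offset(_trace(v + 4.0), _trace(v), lag_samples=0)
    assert res.offset == pytest.approx(4.0, abs=1e-9)
    assert np.allclose(res.imu_aligned.values, res.mocap_aligned.values, atol=1e-9)


def test_align_crops_positive_lag():
    v = np.concatenate([np.zeros(90), 10 * np.sin(np.linspace(0, 3 * np.pi, 300))])
    delayed = np.concatenate([np.zeros(15), v])
    res = align_and_remove_offset(_trace(delayed), _trace(v), lag_samples=15)
    assert res.lag_seconds == pytest.approx(0.5)
    assert len(res.imu_aligned) == len(res.mocap_aligned)
    assert np.allclose(res.imu_aligned.values, res.mocap_aligned.values, atol=1e-12)


def test_align_rejects_disjoint_traces():
    with pytest.raises(ValueError, match="overlap"):
        align_and_remove_offset(_trace(np.zeros(10)), _trace(np.zeros(10)), lag_samples=9)


def test_end_to_end_lag_and_offset_on_synthetic_session(noisy_session):
    from kinagree import process_session

    res = process_session(noisy_session)
    assert res.sync.lag_samples == noisy_session.truth.lag_samples
    # offset convention: IMU rest mean minus MoCap rest mean = -injected offset
    assert res.sync.offset == pytest.approx(-noisy_session.truth.offset, abs=0.5)


def test_sync_stage_is_idempotent(noisy_session):
    from kinagree.orientation import segment_angle_trace

    imu_angle = segment_angle_trace(noisy_session.imu_stream, "z")
    mocap30 = downsample_to_imu_rate(noisy_session.mocap_trace)
    lag = estimate_session_lag(
        noisy_session.imu_stream.acc[:, 0], mocap30.marker
    )
    first = align_and_remove_offset(imu_angle, mocap30, lag, rest_window=2.0)
    again = align_and_remove_offset(
        first.imu_aligned, first.mocap_aligned, 0, rest_window=2.0
    )
    assert abs(again.offset) < 1e-9  # offset already removed
    assert np.allclose(again.imu_aligned.values, first.imu_aligned.values)


def test_native_30hz_rendering_agrees_with_downsampled_path(clean_session):
    """The generator's 30 Hz IMU rendering and the downsample-then-extract
    MoCap path describe the same band-limited truth within 2 % RMS."""
    from kinagree.orientation import segment_angle_trace

    imu = segment_angle_trace(clean_session.imu_stream, "z").values
    mocap = downsample_to_imu_rate(clean_session.mocap_trace).values
    n = min(imu.size, mocap.size)
    rms_diff = np.sqrt(np.mean((imu[20 : n - 20] - mocap[20 : n - 20]) ** 2))
    rms_signal = np.sqrt(np.mean(mocap[20 : n - 20] ** 2))
    assert rms_diff < 0.02 * rms_signal
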