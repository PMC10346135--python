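"""Agreement-statistics suite: worked accuracy examples, hand-arithmetic and
brute-force moment oracles, Monte-Carlo checks of Bland-Altman coverage and
the Anderson-Darling test, and the CCC <= PCC property."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinagree import REFERENCE_ROM
from kinagree.agreement import (
    AgreementReport,
    PairedROMSample,
    accuracy,
    anderson_darling,
    bland_altman,
    build_report,
    lin_ccc,
    pearson,
    rmse,
    sem_from_sds,
    sem_mcid,
)


# ----------------------------------------------------------------- accuracy


def test_accuracy_reproduces_reference_semi_squat_row():
    assert accuracy(33.92, 34.80) == pytest.approx(97.5, abs=0.05)


def test_accuracy_reproduces_reference_hip_extension_row():
    assert accuracy(17.08, 23.40) == pytest.approx(73.0, abs=0.05)


def test_accuracy_of_identical_means_is_100():
    assert accuracy(28.4, 28.4) == 100.0


def test_accuracy_is_scale_invariant():
    assert accuracy(3 * 30.28, 3 * 31.32) == pytest.approx(accuracy(30.28, 31.32))


def test_accuracy_rejects_zero_reference():
    with pytest.raises(ZeroDivisionError):
        accuracy(10.0, 0.0)


# --------------------------------------------------------------------- rmse


def test_rmse_examples():
    assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
    assert rmse([5.0], [2.0]) == 3.0
    # diffs (3, -4): sqrt(25/2)
    assert rmse([3.0, -4.0], [0.0, 0.0]) == pytest.approx(np.sqrt(12.5))


def test_rmse_rejects_length_mismatch():
    with pytest.raises(ValueError):
        rmse([1.0, 2.0], [1.0])


# ------------------------------------------------------------- correlations


def test_pearson_on_perfect_lines():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    r, _ = pearson(x, x)
    assert r == pytest.approx(1.0)
    r, _ = pearson(x, -2 * x + 5)
    assert r == pytest.approx(-1.0)


def test_pearson_matches_textbook_formula_on_fixture():
    x = np.array([30.1, 28.4, 35.2, 31.0, 26.8])
    y = np.array([29.0, 29.5, 33.8, 30.2, 28.1])
    # direct formula oracle
    num = np.sum((x - x.mean()) * (y - y.mean()))
    den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    r, p = pearson(x, y)
    assert r == pytest.approx(num / den, abs=1e-12)
    assert 0.0 < p < 1.0


def test_pearson_rejects_zero_variance():
    with pytest.raises(ValueError, match="variance"):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_ccc_is_one_for_identity():
    x = np.array([10.0, 20.0, 30.0, 40.0])
    assert lin_ccc(x, x) == pytest.approx(1.0)


def test_ccc_penalizes_location_shift():
    x = np.array([10.0, 20.0, 30.0, 40.0])
    c = lin_ccc(x, x + 10.0)
    r, _ = pearson(x, x + 10.0)
    assert r == pytest.approx(1.0)
    assert c < 1.0


def test_ccc_matches_brute_force_moments():
    x = np.array([30.1, 28.4, 35.2, 31.0, 26.8, 33.3])
    y = np.array([29.0, 29.5, 33.8, 30.2, 28.1, 30.9])
    n = x.size
    sx2 = np.sum((x - x.mean()) ** 2) / n
    sy2 = np.sum((y - y.mean()) ** 2) / n
    sxy = np.sum((x - x.mean()) * (y - y.mean())) / n
    expected = 2 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)
    assert lin_ccc(x, y) == pytest.approx(expected, abs=1e-12)


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(st.floats(-100, 100), min_size=3, max_size=25),
    st.integers(0, 2**31 - 1),
)
def test_ccc_magnitude_never_exceeds_pcc(xs, seed):
    x = np.asarray(xs)
    rng = np.random.default_rng(seed)
    y = rng.normal(0.0, 10.0, x.size)
    if x.std() == 0 or y.std() == 0:
        return
    r, _ = pearson(x, y)
    assert abs(lin_ccc(x, y)) <= abs(r) + 1e-12


# ------------------------------------------------------------- bland-altman


def test_bland_altman_identical_vectors():
    x = np.array([1.0, 2.0, 3.0])
    ba = bland_altman(x, x)
    assert (ba.bias, ba.loa_low, ba.loa_high) == (0.0, 0.0, 0.0)


def test_bland_altman_constant_difference_collapses_loa():
    x = np.array([1.0, 2.0, 3.0])
    ba = bland_altman(x + 2.5, x)
    assert ba.bias == pytest.approx(2.5)
    assert ba.loa_low == pytest.approx(2.5)
    assert ba.loa_high == pytest.approx(2.5)


def test_bland_altman_matches_gaussian_closed_form():
    rng = np.random.default_rng(99)
    n = 10_000
    mocap = rng.normal(30.0, 5.0, n)
    imu = mocap + rng.normal(2.0, 1.0, n)
    ba = bland_altman(imu, mocap)
    assert ba.bias == pytest.approx(2.0, abs=0.05)
    assert ba.loa_low == pytest.approx(2.0 - 1.96, abs=0.1)
    assert ba.loa_high == pytest.approx(2.0 + 1.96, abs=0.1)
    coverage = np.mean((ba.diffs >= ba.loa_low) & (ba.diffs <= ba.loa_high))
    assert 0.93 <= coverage <= 0.97


def test_bland_altman_payload_axes():
    imu = np.array([10.0, 20.0])
    mocap = np.array([12.0, 18.0])
    ba = bland_altman(imu, mocap)
    assert np.allclose(ba.means, [11.0, 19.0])  # x-values: pairwise means
    assert np.allclose(ba.diffs, [-2.0, 2.0])  # y-values: differences


# ----------------------------------------------------------------- sem/mcid


def test_sem_zero_at_perfect_reliability():
    assert sem_mcid(3.0, 1.0)[0] == 0.0


def test_sem_closed_form():
    sem, mcid, _ = sem_mcid(2.0, 0.75)
    assert sem == pytest.approx(1.0)
    assert mcid == pytest.approx(1.0)


def test_reliability_above_one_is_clamped_to_reciprocal():
    sem_hi, _, _ = sem_mcid(2.0, 4.0)
    sem_lo, _, _ = sem_mcid(2.0, 0.25)
    assert sem_hi == pytest.approx(sem_lo)
    assert np.isfinite(sem_hi)


def test_sem_from_sds_is_symmetric_and_flags_mcid():
    a = sem_from_sds(7.34, 9.33, abs_mean_diff=0.88)
    b = sem_from_sds(9.33, 7.34, abs_mean_diff=0.88)
    assert a[0] == pytest.approx(b[0])
    assert a[2] is False  # 0.88 deg below the ~5 deg threshold
    assert sem_from_sds(6.09, 5.90, abs_mean_diff=4.19)[2] is True


def test_negative_sd_rejected():
    with pytest.raises(ValueError):
        sem_mcid(-1.0, 0.5)


# ---------------------------------------------------------------- normality


def test_anderson_darling_type_one_error_rate():
    """~5 % rejections at alpha 0.05 on Gaussian cohorts (n = 200)."""
    rejections = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        _, p = anderson_darling(rng.normal(0.0, 1.0, 200))
        rejections += p < 0.05
    assert 1 <= rejections <= 10


def test_anderson_darling_rejects_uniform_data():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        _, p = anderson_darling(rng.uniform(0.0, 1.0, 200))
        hits += p < 0.01
    assert hits >= 19


def test_anderson_darling_degenerate_inputs():
    with pytest.raises(ValueError):
        anderson_darling(np.full(50, 3.0))
    with pytest.raises(ValueError):
        anderson_darling(np.arange(5.0))


# ------------------------------------------------------------------- report


def test_report_perfect_agreement_limit():
    x = np.array([28.0, 31.0, 34.0, 30.0, 29.5, 33.0, 27.5, 32.0])
    rep = build_report(PairedROMSample(x, x, "hip_flexion"))
    assert rep.accuracy == 100.0
    assert rep.rmse == 0.0
    assert rep.pcc == pytest.approx(1.0)
    assert rep.ccc == pytest.approx(1.0)
    assert (rep.ba_bias, rep.ba_loa_low, rep.ba_loa_high) == (0.0, 0.0, 0.0)
    assert rep.sem == pytest.approx(0.0)
    assert not rep.mcid_exceeded


def test_report_flags_bias_exceeding_mcid(rng):
    mocap = rng.normal(30.0, 5.0, 21)
    imu = mocap + 6.0 + rng.normal(0.0, 0.5, 21)
    rep = build_report(PairedROMSample(imu, mocap, "hip_extension"))
    assert rep.abs_diff == pytest.approx(6.0, abs=0.5)
    if rep.abs_diff > rep.mcid:
        assert rep.mcid_exceeded
    assert rep.ba_loa_low <= rep.ba_bias <= rep.ba_loa_high
    assert rep.rmse >= abs(rep.ba_bias)
    assert abs(rep.ccc) <= abs(rep.pcc) + 1e-12


def test_report_round_trips_through_json(rng):
    mocap = rng.normal(30.0, 5.0, 12)
    imu = mocap + rng.normal(1.0, 1.0, 12)
    rep = build_report(PairedROMSample(imu, mocap, "semi-squat"))
    restored = AgreementReport.from_dict(json.loads(rep.to_json()))
    assert restored == rep


def test_rmse_decomposition_into_bias_and_variance(rng):
    """Population identity RMSE^2 = bias^2 + var(diff) on a large sample."""
    n = 100_000
    mocap = rng.normal(30.0, 5.0, n)
    imu = mocap + rng.normal(2.0, 1.5, n)
    ba = bland_altman(imu, mocap)
    lhs = rmse(imu, mocap) ** 2
    rhs = ba.bias**2 + np.var(imu - mocap)
    assert lhs == pytest.approx(rhs, rel=1e-6)


def test_reference_table_mean_error_is_below_five_degrees():
    diffs = [abs(r.imu_mean - r.mocap_mean) for r in REFERENCE_ROM.values()]
    assert np.mean(diffs) < 5.0
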