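"""Method-agreement statistics between paired per-participant ROM means.

Implements the full suite used to validate a new measurement system
against a gold standard: percent accuracy of the cohort means, RMSE over
paired per-participant values, Pearson and Lin concordance correlation,
Bland-Altman bias and 95 % limits of agreement, the standard error of
measurement (SEM) with a 1-SEM minimal clinically important difference
(MCID) flag, and an Anderson-Darling normality check.

Definitions
-----------
accuracy  = (1 - |ROM_new - ROM_ref| / ROM_ref) * 100
RMSE      = sqrt(sum_i (y_hat_i - y_i)^2 / n)
CCC       = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2)   (1/n moments,
            the original concordance estimator's convention)
LoA       = bias +/- 1.96 sd(differences)
SEM       = SD_pooled * sqrt(1 - R),  MCID = 1 SEM

The reliability ratio R = var_ref / var_new can exceed 1 on real data,
which would make sqrt(1 - R) undefined; it is clamped to
min(ratio, 1/ratio) and paired with the pooled SD
sqrt((SD_new^2 + SD_ref^2) / 2), keeping the SEM real and symmetric in
the two systems. This clamping is a documented convention of this
package, not a property of the published formula.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedROMSample",
    "BlandAltman",
    "AgreementReport",
    "accuracy",
    "rmse",
    "pearson",
    "lin_ccc",
    "bland_altman",
    "sem_mcid",
    "sem_from_sds",
    "anderson_darling",
    "build_report",
]


@dataclass(frozen=True)
class PairedROMSample:
    """Per-participant mean ROM pairs (imu_i, mocap_i), i = 1..n, one task."""

    imu: np.ndarray
    mocap: np.ndarray
    task_name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "imu", np.asarray(self.imu, dtype=float))
        object.__setattr__(self, "mocap", np.asarray(self.mocap, dtype=float))
        if self.imu.shape != self.mocap.shape or self.imu.ndim != 1:
            raise ValueError("imu and mocap must be equal-length 1-D vectors")
        if self.imu.size < 2:
            raise ValueError("at least 2 participants required")

    @property
    def n(self) -> int:
        return int(self.imu.size)


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray  # (imu_i + mocap_i) / 2, the plot's x-values
    diffs: np.ndarray  # imu_i - mocap_i, the plot's y-values


def accuracy(rom_imu_mean: float, rom_mocap_mean: float) -> float:
    """Percent accuracy of the device mean relative to the reference mean."""
    if rom_mocap_mean == 0:
        raise ZeroDivisionError("reference ROM mean is zero; accuracy undefined")
    return (1.0 - abs(rom_imu_mean - rom_mocap_mean) / rom_mocap_mean) * 100.0


def rmse(imu_values, mocap_values) -> float:
    """Root mean square error over paired values."""
    a = np.asarray(imu_values, dtype=float)
    b = np.asarray(mocap_values, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("inputs must be equal-length non-empty vectors")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def pearson(imu_values, mocap_values) -> tuple[float, float]:
    """Pearson correlation and its two-sided p-value (t transform)."""
    a = np.asarray(imu_values, dtype=float)
    b = np.asarray(mocap_values, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("at least 3 paired values required")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = stats.pearsonr(a, b)
    return float(r.statistic), float(r.pvalue)


def lin_ccc(imu_values, mocap_values) -> float:
    """Lin's concordance correlation coefficient (1/n sample moments)."""
    x = np.asarray(imu_values, dtype=float)
    y = np.asarray(mocap_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("at least 3 paired values required")
    sx2 = float(np.var(x))  # 1/n
    sy2 = float(np.var(y))
    if sx2 == 0 and sy2 == 0:
        raise ValueError("concordance undefined when both inputs are constant")
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    return 2.0 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)


def bland_altman(imu_values, mocap_values) -> BlandAltman:
    """Bias and 95 % limits of agreement of the per-participant differences."""
    a = np.asarray(imu_values, dtype=float)
    b = np.asarray(mocap_values, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("inputs must be equal-length non-empty vectors")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(a + b) / 2.0,
        diffs=d,
    )


def sem_mcid(
    sd_pooled: float, reliability_r: float, abs_mean_diff: float | None = None
) -> tuple[float, float, bool | None]:
    """Standard error of measurement and 1-SEM MCID threshold.

    ``SEM = SD * sqrt(1 - R)``. A reliability ratio above 1 (possible when
    R is estimated as a variance ratio) is clamped to its reciprocal so the
    square root stays real. Returns ``(sem, mcid, exceeded)`` where
    ``exceeded`` flags ``|mean difference| > MCID`` (None when no mean
    difference is supplied).
    """
    if sd_pooled < 0:
        raise ValueError("standard deviation must be non-negative")
    if reliability_r < 0:
        raise ValueError("reliability must be non-negative")
    if reliability_r > 1.0:
        reliability_r = 1.0 / reliability_r
    sem = sd_pooled * math.sqrt(1.0 - reliability_r)
    mcid = sem
    exceeded = None if abs_mean_diff is None else bool(abs_mean_diff > mcid)
    return sem, mcid, exceeded


def sem_from_sds(
    sd_imu: float, sd_mocap: float, abs_mean_diff: float | None = None
) -> tuple[float, float, bool | None]:
    """SEM/MCID from the two systems' SDs.

    The reliability ratio is ``var_mocap / var_imu`` (clamped inside
    :func:`sem_mcid`) and the SD is the pooled
    ``sqrt((sd_imu^2 + sd_mocap^2) / 2)`` — symmetric in the two systems.
    """
    if sd_imu < 0 or sd_mocap < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd_imu == 0 and sd_mocap == 0:
        exceeded = None if abs_mean_diff is None else bool(abs_mean_diff > 0)
        return 0.0, 0.0, exceeded
    ratio = (sd_mocap / sd_imu) ** 2 if sd_imu > 0 else 0.0
    sd_pooled = math.sqrt((sd_imu**2 + sd_mocap**2) / 2.0)
    return sem_mcid(sd_pooled, ratio, abs_mean_diff=abs_mean_diff)


# D'Agostino & Stephens small-sample correction and p-value for the
# Anderson-Darling statistic under the composite normal hypothesis
# (both parameters estimated) — the approximation standard statistical
# packages use.
def anderson_darling(values) -> tuple[float, float]:
    """Anderson-Darling normality test: (A2 statistic, approximate p-value)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 8:
        raise ValueError("Anderson-Darling p approximation needs n >= 8")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("normality test undefined for a constant vector")
    z = stats.norm.cdf((x - x.mean()) / s)
    z = np.clip(z, 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(z) + np.log1p(-z[::-1])))
    a2_star = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2_star >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2_star + 0.0186 * a2_star**2)
    elif a2_star >= 0.34:
        p = math.exp(0.9177 - 4.279 * a2_star - 1.38 * a2_star**2)
    elif a2_star >= 0.2:
        p = 1.0 - math.exp(-8.318 + 42.796 * a2_star - 59.938 * a2_star**2)
    else:
        p = 1.0 - math.exp(-13.436 + 101.14 * a2_star - 223.73 * a2_star**2)
    return float(a2), float(min(max(p, 0.0), 1.0))


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement summary for one task (all angles in degrees)."""

    task_name: str
    n: int
    mean_rom_imu: float
    sd_imu: float
    mean_rom_mocap: float
    sd_mocap: float
    abs_diff: float
    accuracy: float  # percent
    rmse: float
    pcc: float
    pcc_p: float
    ccc: float
    ba_bias: float
    ba_loa_low: float
    ba_loa_high: float
    sem: float
    mcid: float
    mcid_exceeded: bool
    normality_p: float  # Anderson-Darling p of the differences (nan if degenerate)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "AgreementReport":
        return cls(**d)


def build_report(sample: PairedROMSample) -> AgreementReport:
    """Compute every agreement statistic for one task's paired cohort sample."""
    imu, mocap = sample.imu, sample.mocap
    mean_imu, mean_mc = float(imu.mean()), float(mocap.mean())
    sd_imu = float(imu.std(ddof=1))
    sd_mc = float(mocap.std(ddof=1))
    abs_diff = abs(mean_imu - mean_mc)
    ba = bland_altman(imu, mocap)
    try:
        pcc, pcc_p = pearson(imu, mocap)
    except ValueError:
        pcc, pcc_p = float("nan"), float("nan")
    try:
        ccc = lin_ccc(imu, mocap)
    except ValueError:
        ccc = float("nan")
    sem, mcid, exceeded = sem_from_sds(sd_imu, sd_mc, abs_mean_diff=abs_diff)
    try:
        _, norm_p = anderson_darling(ba.diffs)
    except ValueError:
        norm_p = float("nan")
    return AgreementReport(
        task_name=sample.task_name,
        n=sample.n,
        mean_rom_imu=mean_imu,
        sd_imu=sd_imu,
        mean_rom_mocap=mean_mc,
        sd_mocap=sd_mc,
        abs_diff=abs_diff,
        accuracy=accuracy(mean_imu, mean_mc),
        rmse=rmse(imu, mocap),
        pcc=pcc,
        pcc_p=pcc_p,
        ccc=ccc,
        ba_bias=ba.bias,
        ba_loa_low=ba.loa_low,
        ba_loa_high=ba.loa_high,
        sem=sem,
        mcid=mcid,
        mcid_exceeded=bool(exceeded),
        normality_p=norm_p,
    )
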