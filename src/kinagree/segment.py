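"""Repetition segmentation, cycle normalization and the working-phase ROM statistic.

Repetitions are located from the local minima separating successive
excursions; each cycle is resampled to a fixed number of points (101, the
gait-cycle convention) and amplitude-normalized, and the *working phase* —
the longest contiguous run where the normalized angle stays at or above a
threshold ``tau`` of the excursion — is isolated. The per-repetition ROM
is the mean raw angle over the working phase minus the rest baseline:
because the subject holds the target excursion under biofeedback, this
plateau mean describes how well the maximum ROM is maintained, which a
naive max-minus-min statistic does not (a single overshoot sample would
dominate it). Max-minus-min and a final-position variant are kept as
secondary diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .traces import AngleTrace

__all__ = [
    "RepetitionSet",
    "ROMEstimate",
    "SegmentationError",
    "detect_repetitions",
    "resample_cycle",
    "working_phase",
    "compute_rom",
    "rom_max_min",
    "rom_estimate_for_trace",
    "side_difference_p",
    "pool_sides",
]

DEFAULT_N_POINTS = 101
DEFAULT_TAU = 0.9


class SegmentationError(RuntimeError):
    """The trace does not contain identifiable repetitions."""


@dataclass(frozen=True)
class RepetitionSet:
    """Detected repetitions of one trace.

    ``boundaries`` holds the n+1 sample indices delimiting the n cycles;
    ``cycles`` is an (n, n_points) array of the raw (un-normalized) angle
    values of each cycle resampled to ``n_points`` samples.
    """

    boundaries: np.ndarray
    cycles: np.ndarray
    n_points: int

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries)
        if b.size < 2 or np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing, length >= 2")
        if self.cycles.shape != (b.size - 1, self.n_points):
            raise ValueError("cycles must be (n_boundaries - 1, n_points)")

    @property
    def n_cycles(self) -> int:
        return self.cycles.shape[0]


@dataclass(frozen=True)
class ROMEstimate:
    """Per-repetition ROM values (degrees) for one task/system/side."""

    per_rep_rom: np.ndarray
    task_name: str
    system: str
    side: str = ""  # "", "left", "right"
    pooled: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "per_rep_rom", np.asarray(self.per_rep_rom, dtype=float)
        )
        if self.per_rep_rom.size == 0:
            raise ValueError("ROMEstimate requires at least one repetition")

    @property
    def mean_rom(self) -> float:
        return float(np.mean(self.per_rep_rom))

    @property
    def sd_rom(self) -> float:
        return float(np.std(self.per_rep_rom, ddof=1)) if self.per_rep_rom.size > 1 else 0.0

    @property
    def n_reps(self) -> int:
        return int(self.per_rep_rom.size)


def detect_repetitions(
    trace: AngleTrace,
    expected_n: int | None = None,
    prominence_frac: float = 0.25,
    n_points: int = DEFAULT_N_POINTS,
    smooth_window: float = 0.3,
) -> RepetitionSet:
    """Segment an aligned, offset-free trace into repetitions.

    The trace is lightly smoothed (moving average over ``smooth_window``
    seconds) for detection only; excursion peaks with prominence at least
    ``prominence_frac`` of the global excursion are located, and peaks not
    separated by a valley descending at least that same fraction are merged
    into one repetition (a flat plateau can carry several numerically tied
    micro-peaks). Cycle boundaries are placed at the local minimum between
    consecutive repetition peaks, plus the minima preceding the first and
    following the last peak. A count different from ``expected_n`` raises
    a warning with diagnostics, never a silent truncation.
    """
    v_raw = trace.values
    w = max(1, int(round(smooth_window * trace.rate)))
    if w > 1:
        padded = np.pad(v_raw, w, mode="edge")
        v = np.convolve(padded, np.ones(w) / w, mode="same")[w:-w]
    else:
        v = v_raw
    excursion = float(v.max() - v.min())
    if excursion <= 1e-9:
        raise SegmentationError("constant trace: no repetitions to segment")
    prom = prominence_frac * excursion
    peaks, _ = sps.find_peaks(v, prominence=prom)
    if peaks.size < 1:
        raise SegmentationError(
            f"no excursion with prominence >= {prominence_frac:.0%} of range"
        )
    # merge peaks that share an excursion: a true repetition boundary must
    # dip at least `prom` below the lower of the flanking peaks
    groups: list[list[int]] = [[int(peaks[0])]]
    for p_prev, p in zip(peaks[:-1], peaks[1:]):
        valley = float(v[p_prev : p + 1].min())
        if valley <= min(v[p_prev], v[p]) - prom:
            groups.append([int(p)])
        else:
            groups[-1].append(int(p))
    rep_peaks = np.array([g[int(np.argmax(v[g]))] for g in groups], dtype=int)
    bounds = [int(np.argmin(v[: rep_peaks[0]])) if rep_peaks[0] > 0 else 0]
    for p0, p1 in zip(rep_peaks[:-1], rep_peaks[1:]):
        bounds.append(int(p0 + np.argmin(v[p0:p1])))
    tail = v[rep_peaks[-1] :]
    bounds.append(int(rep_peaks[-1] + (np.argmin(tail) if tail.size else 0)))
    if bounds[-1] <= bounds[-2]:
        bounds[-1] = v_raw.size - 1
    boundaries = np.asarray(bounds, dtype=int)
    if expected_n is not None and rep_peaks.size != expected_n:
        warnings.warn(
            f"detected {rep_peaks.size} repetitions but expected {expected_n} "
            f"(peaks at samples {rep_peaks.tolist()})",
            stacklevel=2,
        )
    v = v_raw  # cycles are cut from the raw, unsmoothed trace
    cycles = np.vstack(
        [
            resample_cycle(v[a : b + 1], n_points)
            for a, b in zip(boundaries[:-1], boundaries[1:])
        ]
    )
    return RepetitionSet(boundaries=boundaries, cycles=cycles, n_points=n_points)


def resample_cycle(cycle: np.ndarray, n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Linear-interpolation resample of one cycle to ``n_points`` samples.

    Endpoint values are preserved exactly; affine segments resample exactly.
    """
    cycle = np.asarray(cycle, dtype=float)
    if cycle.size < 4:
        raise ValueError(f"cycle too short to resample ({cycle.size} samples)")
    x_old = np.linspace(0.0, 1.0, cycle.size)
    x_new = np.linspace(0.0, 1.0, n_points)
    return np.interp(x_new, x_old, cycle)


def working_phase(
    cycle: np.ndarray, tau: float = DEFAULT_TAU, smooth_window: int = 5
) -> tuple[int, int]:
    """Half-open index window of the working phase of one cycle.

    The cycle is amplitude-normalized to [0, 1]; the working phase is the
    longest contiguous run with normalized value >= ``tau``. With
    ``tau = 1`` only the argmax sample(s) remain.

    The window is located on a lightly smoothed copy (moving average of
    ``smooth_window`` samples): thresholding the raw samples would tie the
    selection to each sample's own noise — the noisy maximum inflates the
    threshold and only positive-noise samples survive it, biasing the
    working-phase mean upward. Selecting on the smoothed cycle (and
    averaging raw values elsewhere) removes that selection bias while
    leaving noise-free cycles essentially untouched.
    """
    cycle = np.asarray(cycle, dtype=float)
    if smooth_window > 1:
        w = int(smooth_window)
        padded = np.pad(cycle, w, mode="edge")
        cycle = np.convolve(padded, np.ones(w) / w, mode="same")[w:-w]
    lo, hi = float(cycle.min()), float(cycle.max())
    if hi - lo <= 1e-12:
        raise ValueError("flat cycle: working phase undefined")
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must lie in (0, 1]")
    normalized = (cycle - lo) / (hi - lo)
    above = normalized >= tau - 1e-12
    # longest run of True
    best_start = best_len = 0
    start = None
    for i, flag in enumerate(np.append(above, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    if best_len == 0:
        raise ValueError("empty working phase")
    return best_start, best_start + best_len


def compute_rom(
    cycle: np.ndarray,
    rest_value: float = 0.0,
    tau: float = DEFAULT_TAU,
    mode: str = "working_mean",
) -> float:
    """Per-repetition ROM (degrees) of one raw cycle.

    ``mode="working_mean"`` (default): mean raw angle over the working
    phase minus ``rest_value``. ``mode="final_position"``: last
    working-phase sample minus ``rest_value``, the literal end-of-plateau
    variant kept for comparison. The window comes from the smoothed cycle
    (see :func:`working_phase`); the averaged values are the raw ones.
    """
    cycle = np.asarray(cycle, dtype=float)
    i0, i1 = working_phase(cycle, tau=tau)
    if mode == "working_mean":
        return float(np.mean(cycle[i0:i1]) - rest_value)
    if mode == "final_position":
        return float(cycle[i1 - 1] - rest_value)
    raise ValueError(f"unknown ROM mode {mode!r}")


def rom_max_min(cycle: np.ndarray) -> float:
    """Secondary diagnostic: raw max-minus-min excursion of one cycle."""
    cycle = np.asarray(cycle, dtype=float)
    return float(cycle.max() - cycle.min())


def rom_estimate_for_trace(
    trace: AngleTrace,
    expected_n: int | None = None,
    rest_value: float | None = None,
    tau: float = DEFAULT_TAU,
    rest_window: float = 1.0,
    prominence_frac: float = 0.25,
    n_points: int = DEFAULT_N_POINTS,
    side: str = "",
) -> ROMEstimate:
    """Segment a trace and compute the working-phase ROM of every repetition.

    ``rest_value`` defaults to the mean of the first ``rest_window``
    seconds of the trace (the pre-task rest).
    """
    if rest_value is None:
        n_rest = max(1, int(round(rest_window * trace.rate)))
        rest_value = float(np.mean(trace.values[:n_rest]))
    reps = detect_repetitions(
        trace, expected_n=expected_n, prominence_frac=prominence_frac, n_points=n_points
    )
    roms = np.array(
        [compute_rom(c, rest_value=rest_value, tau=tau) for c in reps.cycles]
    )
    return ROMEstimate(
        per_rep_rom=roms, task_name=trace.task_name, system=trace.system, side=side
    )


def side_difference_p(left: ROMEstimate, right: ROMEstimate) -> float:
    """p-value of a paired two-sample comparison of per-repetition ROMs.

    Used as the pre-test for pooling bilateral tasks: sides are pooled only
    when the difference is non-significant. A paired t-test on matched
    repetition indices is used (falls back to Welch's t when the sides have
    unequal repetition counts).
    """
    a, b = left.per_rep_rom, right.per_rep_rom
    if a.size == b.size:
        if np.allclose(a, b):
            return 1.0
        return float(stats.ttest_rel(a, b).pvalue)
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def pool_sides(left: ROMEstimate, right: ROMEstimate) -> ROMEstimate:
    """Concatenate per-repetition ROMs of the two sides of a bilateral task."""
    if left.task_name != right.task_name or left.system != right.system:
        raise ValueError("can only pool sides of the same task and system")
    return ROMEstimate(
        per_rep_rom=np.concatenate([left.per_rep_rom, right.per_rep_rom]),
        task_name=left.task_name,
        system=left.system,
        side="pooled",
        pooled=True,
    )
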