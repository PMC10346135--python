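"""Reference cohort summary statistics for the seven motor tasks.

These are the published validation-cohort numbers (21 healthy adults, 10
repetitions per task, thigh/trunk-worn IMU vs an 8-camera optoelectronic
system) that the rest of the package uses as inputs: the MoCap ROM means
serve as default task amplitudes for the synthetic-session generator, and
the per-system means feed the worked accuracy examples.

All angles are degrees, accuracies percent.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "TASKS",
    "BILATERAL_TASKS",
    "ReferenceRow",
    "REFERENCE_ROM",
    "REFERENCE_CORRELATION",
    "REFERENCE_MISPLACEMENT",
]

#: Canonical task vocabulary (device exercise library subset used in the study).
TASKS = (
    "semi-squat",
    "hip_abduction",
    "hip_flexion",
    "hip_extension",
    "knee_extension",
    "trunk_flexion",
    "trunk_bending",
)

#: Tasks performed on both sides (10 repetitions per side, pooled to 20).
BILATERAL_TASKS = frozenset(
    {"hip_abduction", "hip_flexion", "hip_extension", "knee_extension", "trunk_bending"}
)


@dataclass(frozen=True)
class ReferenceRow:
    """Per-task cohort summary: mean (SD) ROM per system plus agreement figures."""

    imu_mean: float
    imu_sd: float
    mocap_mean: float
    mocap_sd: float
    accuracy_pct: float
    rmse: float
    mcid: float


#: Cohort ROM summary per task: IMU vs MoCap mean (SD), accuracy, RMSE, MCID (= 1 SEM).
REFERENCE_ROM: dict[str, ReferenceRow] = {
    "semi-squat": ReferenceRow(33.92, 7.34, 34.80, 9.33, 97.5, 3.71, 5.00),
    "hip_abduction": ReferenceRow(30.93, 6.09, 35.12, 5.90, 88.1, 6.38, 1.74),
    "hip_flexion": ReferenceRow(30.28, 5.24, 31.32, 5.17, 96.7, 3.68, 1.85),
    "hip_extension": ReferenceRow(17.08, 3.75, 23.40, 4.26, 73.0, 8.47, 3.78),
    "knee_extension": ReferenceRow(71.05, 10.28, 66.15, 9.95, 92.6, 5.90, 1.57),
    "trunk_flexion": ReferenceRow(40.15, 8.36, 30.15, 5.50, 66.8, 14.55, 8.07),
    "trunk_bending": ReferenceRow(26.53, 5.33, 30.10, 6.06, 88.1, 4.49, 3.24),
}

#: Per-task (Pearson, Lin concordance) correlation between the two systems.
REFERENCE_CORRELATION: dict[str, tuple[float, float]] = {
    "semi-squat": (0.95, 0.94),
    "hip_abduction": (0.82, 0.76),
    "hip_flexion": (0.86, 0.90),
    "hip_extension": (0.75, 0.43),
    "knee_extension": (0.95, 0.92),
    "trunk_flexion": (0.68, 0.52),
    "trunk_bending": (0.95, 0.83),
}

#: Misplacement sensitivity summary for the two hip tasks:
#: (correct mean, sd), (medial mean, sd), (lateral mean, sd), rmse_medial, rmse_lateral.
REFERENCE_MISPLACEMENT: dict[str, dict[str, tuple[float, float] | float]] = {
    "hip_flexion": {
        "correct": (30.28, 5.24),
        "medial": (28.90, 4.88),
        "lateral": (27.70, 5.79),
        "rmse_medial": 5.12,
        "rmse_lateral": 5.13,
    },
    "hip_extension": {
        "correct": (17.08, 3.75),
        "medial": (19.98, 3.36),
        "lateral": (11.90, 3.61),
        "rmse_medial": 4.86,
        "rmse_lateral": 7.09,
    },
}
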