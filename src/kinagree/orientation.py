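"""Quaternion / rotation-matrix / Euler-angle conversions for the two systems.

The IMU-based device decomposes its orientation quaternion with an intrinsic
ZYX rotation sequence (first angle = flexion/extension, middle =
internal/external rotation, last = adduction/abduction); the optoelectronic
reference decomposes its segment rotation matrices with an intrinsic YXZ
sequence (flexion/extension, adduction/abduction, internal/external).
Both sequences are interpreted as intrinsic rotations, the convention of
commercial IMU firmware and standard gait software.

Angles are degrees everywhere at the API surface; scipy's
:class:`~scipy.spatial.transform.Rotation` does the heavy lifting internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .traces import AngleTrace, QuatStream

__all__ = [
    "EulerAngles",
    "GimbalLockWarning",
    "quat_to_euler_zyx",
    "euler_zyx_to_quat",
    "rotmat_to_euler_yxz",
    "euler_yxz_to_rotmat",
    "segment_angle_trace",
]

#: middle-angle proximity (degrees) at which the decomposition is flagged
GIMBAL_GUARD_DEG = 89.99

_UNIT_TOL = 1e-6
_ORTHO_TOL = 1e-9


class GimbalLockWarning(UserWarning):
    """Middle Euler angle is within numerical reach of +/-90 degrees."""


@dataclass(frozen=True)
class EulerAngles:
    """One Euler-angle triplet in the anatomical naming of its sequence.

    ``sequence_tag`` is ``"ZYX"`` (IMU convention: flexion, internal/external,
    adduction/abduction) or ``"YXZ"`` (MoCap convention: flexion,
    adduction/abduction, internal/external). All angles in degrees.
    """

    flexion_extension: float
    adduction_abduction: float
    internal_external: float
    sequence_tag: str

    def as_sequence(self) -> np.ndarray:
        """Angles ordered as the rotations are applied (intrinsic)."""
        if self.sequence_tag == "ZYX":
            return np.array(
                [self.flexion_extension, self.internal_external, self.adduction_abduction]
            )
        return np.array(
            [self.flexion_extension, self.adduction_abduction, self.internal_external]
        )


def _check_unit(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    norms = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
        worst = float(np.max(np.abs(norms - 1.0)))
        raise ValueError(f"quaternion norm deviates from 1 by {worst:.3g}")
    return q / norms[..., None]


def _warn_gimbal(middle_deg: np.ndarray) -> None:
    if np.any(np.abs(middle_deg) > GIMBAL_GUARD_DEG):
        warnings.warn(
            "middle Euler angle within 0.01 deg of gimbal lock; "
            "first/last angles are not uniquely determined",
            GimbalLockWarning,
            stacklevel=3,
        )


def _rot_from_quat_wxyz(q: np.ndarray) -> Rotation:
    q = np.asarray(q, dtype=float)
    return Rotation.from_quat(np.roll(q, -1, axis=-1))  # wxyz -> xyzw


def quat_to_euler_zyx(q) -> EulerAngles:
    """Decompose a unit quaternion ``(w, x, y, z)`` with the IMU's intrinsic ZYX sequence.

    Returns angles in degrees. Raises ``ValueError`` for non-unit input;
    emits :class:`GimbalLockWarning` when the middle angle approaches 90 deg.
    """
    q = _check_unit(np.asarray(q, dtype=float))
    ang = _rot_from_quat_wxyz(q).as_euler("ZYX", degrees=True)
    _warn_gimbal(np.atleast_2d(ang)[..., 1])
    z, y, x = np.asarray(ang, dtype=float).reshape(3)
    return EulerAngles(
        flexion_extension=z,
        internal_external=y,
        adduction_abduction=x,
        sequence_tag="ZYX",
    )


def euler_zyx_to_quat(angles: EulerAngles) -> np.ndarray:
    """Inverse of :func:`quat_to_euler_zyx`; returns a ``(w, x, y, z)`` quaternion."""
    if angles.sequence_tag != "ZYX":
        raise ValueError(f"expected a ZYX triplet, got {angles.sequence_tag}")
    r = Rotation.from_euler("ZYX", angles.as_sequence(), degrees=True)
    return np.roll(r.as_quat(), 1)  # xyzw -> wxyz


def rotmat_to_euler_yxz(m) -> EulerAngles:
    """Decompose a proper-orthogonal 3x3 matrix with the MoCap intrinsic YXZ sequence."""
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {m.shape}")
    if not np.allclose(m @ m.T, np.eye(3), atol=1e-8) or abs(
        np.linalg.det(m) - 1.0
    ) > 1e-8:
        raise ValueError("matrix is not a proper rotation (orthogonal, det +1)")
    ang = Rotation.from_matrix(m).as_euler("YXZ", degrees=True)
    _warn_gimbal(np.atleast_1d(ang[1]))
    y, x, z = ang
    return EulerAngles(
        flexion_extension=y,
        adduction_abduction=x,
        internal_external=z,
        sequence_tag="YXZ",
    )


def euler_yxz_to_rotmat(angles: EulerAngles) -> np.ndarray:
    if angles.sequence_tag != "YXZ":
        raise ValueError(f"expected a YXZ triplet, got {angles.sequence_tag}")
    return Rotation.from_euler("YXZ", angles.as_sequence(), degrees=True).as_matrix()


# Euler component picked per motion plane, in the device's ZYX convention:
# the first (Z) angle is flexion/extension, the sequence's primary plane.
_PLANE_TO_ZYX_INDEX = {"z": 0, "y": 1, "x": 2}


def segment_angle_trace(stream: QuatStream, plane_axis: str = "z") -> AngleTrace:
    """Extract the absolute segment angle along one motion plane from a quaternion stream.

    ``plane_axis`` selects the Euler component of the intrinsic ZYX
    decomposition: ``"z"`` (default) is the flexion/extension angle — the
    device's primary measurement plane — ``"y"`` internal/external rotation,
    ``"x"`` adduction/abduction. Returns an :class:`AngleTrace` in degrees
    at the stream's own rate and clock.
    """
    if len(stream) == 0:
        raise ValueError("empty quaternion stream")
    try:
        idx = _PLANE_TO_ZYX_INDEX[plane_axis.lower()]
    except KeyError:
        raise ValueError(
            f"plane_axis must be one of {sorted(_PLANE_TO_ZYX_INDEX)}, got {plane_axis!r}"
        ) from None
    q = _check_unit(stream.quat)
    ang = _rot_from_quat_wxyz(q).as_euler("ZYX", degrees=True)
    _warn_gimbal(ang[:, 1])
    return AngleTrace(
        values=ang[:, idx],
        rate=stream.rate,
        t0=stream.t0,
        system="IMU",
        task_name=stream.task_name,
    )
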