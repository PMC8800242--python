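"""Rigid-body pose and rotation arithmetic for electromagnetic sensor tracking.

Conventions used throughout the package:

* positions in millimetres, timestamps in seconds, angles in degrees at
  every public boundary (radians may appear internally);
* quaternions are scalar-first ``(w, x, y, z)`` and re-normalized on ingest;
* all coordinate frames are right-handed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "ValidationError",
    "AlignmentError",
    "RigidPose",
    "PoseStream",
    "as_vec3",
    "normalize_quaternion",
    "quaternion_rotation",
    "rotation_quaternion",
    "transform_point",
    "inverse_transform_point",
    "angle_between_unit_vectors",
    "align_streams",
]

#: quaternion norms further than this from 1 indicate corrupt data rather
#: than serialization rounding and are rejected outright
QUAT_NORM_ERROR = 1e-3
#: tolerance for "unit" direction vectors handed to angle computations
UNIT_VECTOR_TOL = 1e-6


class ValidationError(ValueError):
    """An input violates a structural precondition (non-finite value,
    non-unit quaternion, non-monotone timestamps, ...)."""


class AlignmentError(ValueError):
    """Two pose streams cannot be paired sample-by-sample."""


def as_vec3(v) -> np.ndarray:
    """Coerce to a finite float ``(3,)`` array (mm or unit-vector)."""
    a = np.asarray(v, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValidationError(f"non-finite vector component in {a!r}")
    return a


def normalize_quaternion(q, *, max_norm_error: float = QUAT_NORM_ERROR) -> np.ndarray:
    """Return the unit quaternion parallel to ``q`` (scalar-first).

    Raises :class:`ValidationError` if the norm deviates from 1 by more
    than ``max_norm_error`` — such input is corrupt, not merely rounded.
    """
    a = np.asarray(q, dtype=float).reshape(4)
    if not np.all(np.isfinite(a)):
        raise ValidationError("non-finite quaternion component")
    n = float(np.linalg.norm(a))
    if abs(n - 1.0) > max_norm_error:
        raise ValidationError(
            f"quaternion norm {n:.6g} deviates from 1 by more than {max_norm_error:g}"
        )
    return a / n


def quaternion_rotation(q) -> Rotation:
    """Scalar-first quaternion → :class:`scipy.spatial.transform.Rotation`."""
    a = np.asarray(q, dtype=float)
    # scipy stores quaternions scalar-last
    return Rotation.from_quat(np.roll(a, -1, axis=-1))


def rotation_quaternion(rot: Rotation) -> np.ndarray:
    """:class:`Rotation` → scalar-first quaternion(s), canonical sign."""
    return np.roll(rot.as_quat(canonical=True), 1, axis=-1)


@dataclass(frozen=True)
class RigidPose:
    """Timestamped pose of one sensor: position (mm) + unit quaternion."""

    t: float
    position: np.ndarray
    orientation: np.ndarray  # scalar-first (w, x, y, z)

    def __post_init__(self) -> None:
        t = float(self.t)
        if not np.isfinite(t) or t < 0:
            raise ValidationError(f"timestamp must be finite and non-negative, got {t}")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "position", as_vec3(self.position))
        object.__setattr__(self, "orientation", normalize_quaternion(self.orientation))

    @classmethod
    def identity(cls, t: float = 0.0) -> "RigidPose":
        return cls(t=t, position=np.zeros(3), orientation=np.array([1.0, 0, 0, 0]))

    @property
    def rotation(self) -> Rotation:
        return quaternion_rotation(self.orientation)


def transform_point(pose: RigidPose, local) -> np.ndarray:
    """Map a point from the sensor-local frame into the world frame.

    Returns ``R(q) @ local + position``.
    """
    return pose.rotation.apply(as_vec3(local)) + pose.position


def inverse_transform_point(pose: RigidPose, world) -> np.ndarray:
    """Map a world point into the sensor-local frame (exact inverse of
    :func:`transform_point`)."""
    return pose.rotation.inv().apply(as_vec3(world) - pose.position)


def angle_between_unit_vectors(u, v) -> float:
    """Angle in degrees between two unit vectors, in [0, 180].

    Defined as the arc-cosine of the (clamped) dot product; evaluated via
    ``atan2(|u × v|, u · v)``, which is the same quantity but keeps full
    precision for nearly parallel and nearly opposite vectors.
    """
    u = as_vec3(u)
    v = as_vec3(v)
    for name, w in (("u", u), ("v", v)):
        if abs(np.linalg.norm(w) - 1.0) > UNIT_VECTOR_TOL:
            raise ValidationError(f"{name} is not a unit vector (|{name}| = {np.linalg.norm(w):.6g})")
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v))))


@dataclass
class PoseStream:
    """Ordered pose samples for one sensor, nominally uniform-rate.

    Stored as flat arrays (``t``: (n,), ``positions``: (n, 3),
    ``orientations``: (n, 4) scalar-first) for vectorized kinematics;
    ``pose(i)`` materializes a single :class:`RigidPose`.
    """

    sensor_id: str
    t: np.ndarray
    positions: np.ndarray
    orientations: np.ndarray
    rate_hz: float = 60.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float).reshape(-1)
        n = self.t.size
        self.positions = np.asarray(self.positions, dtype=float).reshape(n, 3)
        self.orientations = np.asarray(self.orientations, dtype=float).reshape(n, 4)
        if not self.rate_hz > 0:
            raise ValidationError(f"rate_hz must be positive, got {self.rate_hz}")
        if n == 0:
            return
        if not np.all(np.isfinite(self.t)) or np.any(self.t < 0):
            raise ValidationError("timestamps must be finite and non-negative")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            i = int(np.argmax(np.diff(self.t) <= 0))
            raise ValidationError(f"timestamps not strictly increasing at sample {i + 1}")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("non-finite position component")
        norms = np.linalg.norm(self.orientations, axis=1)
        bad = np.abs(norms - 1.0) > QUAT_NORM_ERROR
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValidationError(
                f"quaternion norm {norms[i]:.6g} at sample {i} deviates from 1 "
                f"by more than {QUAT_NORM_ERROR:g}"
            )
        self.orientations = self.orientations / norms[:, None]

    def __len__(self) -> int:
        return self.t.size

    @property
    def period(self) -> float:
        return 1.0 / self.rate_hz

    def pose(self, i: int) -> RigidPose:
        return RigidPose(t=self.t[i], position=self.positions[i], orientation=self.orientations[i])

    def poses(self):
        return [self.pose(i) for i in range(len(self))]

    def rotations(self) -> Rotation:
        return quaternion_rotation(self.orientations)

    @classmethod
    def from_poses(cls, sensor_id: str, poses, rate_hz: float = 60.0) -> "PoseStream":
        poses = list(poses)
        return cls(
            sensor_id=sensor_id,
            t=np.array([p.t for p in poses]),
            positions=np.array([p.position for p in poses]).reshape(len(poses), 3),
            orientations=np.array([p.orientation for p in poses]).reshape(len(poses), 4),
            rate_hz=rate_hz,
        )


def align_streams(a: PoseStream, b: PoseStream, max_gap_s: float | None = None):
    """Pair each sample of ``a`` with the nearest-in-time sample of ``b``.

    Returns ``(idx_a, idx_b)`` index arrays. Raises
    :class:`AlignmentError` if any pair is separated by more than
    ``max_gap_s`` (default half of ``a``'s sample period).
    """
    if len(a) == 0 or len(b) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    if max_gap_s is None:
        max_gap_s = 0.5 * a.period
    pos = np.searchsorted(b.t, a.t)
    lo = np.clip(pos - 1, 0, len(b) - 1)
    hi = np.clip(pos, 0, len(b) - 1)
    pick = np.where(np.abs(b.t[hi] - a.t) < np.abs(b.t[lo] - a.t), hi, lo)
    gaps = np.abs(b.t[pick] - a.t)
    if np.any(gaps > max_gap_s):
        i = int(np.argmax(gaps))
        raise AlignmentError(
            f"streams {a.sensor_id!r} and {b.sensor_id!r} misaligned: gap "
            f"{gaps[i]:.6g} s at t={a.t[i]:.6g} s exceeds {max_gap_s:.6g} s"
        )
    idx_a = np.arange(len(a))
    return idx_a, pick
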