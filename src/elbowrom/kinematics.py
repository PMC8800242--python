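"""Anatomical frames and the elbow flexion-angle time series.

The humeral frame hangs off three landmarks: its origin is the epicondylar
midpoint, the longitudinal axis points to the greater tubercle, and the
remaining axes come from cross products with the epicondylar offset. The
forearm frame is built the same way from the styloid midpoint and the
epicondylar midpoint. Flexion is the angle between the two frames'
y-axes — 0° with the arm straight, growing toward deep flexion, never
signed (hyperextension folds onto small positive angles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .registration import FOREARM, HUMERUS, Landmark, LandmarkRegistry
from .rigid import (
    PoseStream,
    ValidationError,
    align_streams,
    angle_between_unit_vectors,
    as_vec3,
)

__all__ = [
    "GeometryError",
    "AnatomicalFrame",
    "AngleSeries",
    "midpoint",
    "humerus_frame",
    "forearm_frame",
    "flexion_angle",
    "angle_timeseries",
    "MIN_TRIANGLE_AREA_MM2",
]

logger = logging.getLogger(__name__)

#: landmark triangles thinner than this are considered collinear
MIN_TRIANGLE_AREA_MM2 = 1.0
_ORTHO_TOL = 1e-9


class GeometryError(ValueError):
    """Landmark geometry too degenerate to define a frame."""


def midpoint(a, b) -> np.ndarray:
    """Component-wise mean of two points."""
    return 0.5 * (as_vec3(a) + as_vec3(b))


@dataclass(frozen=True)
class AnatomicalFrame:
    """Origin plus a right-handed orthonormal axis triple (unit vectors)."""

    origin: np.ndarray
    ux: np.ndarray
    uy: np.ndarray
    uz: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", as_vec3(self.origin))
        for name in ("ux", "uy", "uz"):
            v = as_vec3(getattr(self, name))
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValidationError(f"axis {name} is not unit length")
            object.__setattr__(self, name, v)
        if (
            abs(np.dot(self.ux, self.uy)) > 1e-6
            or abs(np.dot(self.uy, self.uz)) > 1e-6
            or abs(np.dot(self.uz, self.ux)) > 1e-6
        ):
            raise ValidationError("axes are not mutually orthogonal")
        if np.linalg.norm(np.cross(self.ux, self.uy) - self.uz) > 1e-6:
            raise ValidationError("axes are not right-handed")


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError(f"cannot normalize near-zero vector for {what}")
    return v / n


def _triangle_area(a, b, c) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(b - a, c - a)))


def humerus_frame(p_tubercle, p_medial, p_lateral) -> AnatomicalFrame:
    """Upper-arm frame from greater tubercle and the two epicondyles.

    Origin at the epicondylar midpoint; z toward the greater tubercle;
    y normal to the plane of the lateral offset and the shaft; x completes
    the right-handed triple.
    """
    p_g = as_vec3(p_tubercle)
    p_m = as_vec3(p_medial)
    p_l = as_vec3(p_lateral)
    if _triangle_area(p_g, p_m, p_l) <= MIN_TRIANGLE_AREA_MM2:
        raise GeometryError("humeral landmarks are collinear or coincident")
    origin = midpoint(p_m, p_l)
    uz = _unit(p_g - origin, "humeral longitudinal axis")
    uy = _unit(np.cross(p_l - origin, uz), "humeral y-axis")
    ux = np.cross(uy, uz)
    return AnatomicalFrame(origin=origin, ux=ux, uy=uy, uz=uz)


def forearm_frame(p_epicondylar_mid, p_radial, p_ulnar) -> AnatomicalFrame:
    """Forearm frame from the styloid pair and the epicondylar midpoint.

    Origin at the styloid midpoint; z toward the elbow (epicondylar
    midpoint); y normal to the plane of the radial offset and the shaft;
    x completes the triple. With the arm straight the y-axis coincides
    with the humeral one, so flexion reads 0°.
    """
    p_lm2 = as_vec3(p_epicondylar_mid)
    p_r = as_vec3(p_radial)
    p_u = as_vec3(p_ulnar)
    if _triangle_area(p_lm2, p_r, p_u) <= MIN_TRIANGLE_AREA_MM2:
        raise GeometryError("forearm landmarks are collinear or coincident")
    origin = midpoint(p_u, p_r)
    fz = _unit(p_lm2 - origin, "forearm longitudinal axis")
    fy = _unit(np.cross(p_r - origin, fz), "forearm y-axis")
    fx = np.cross(fy, fz)
    return AnatomicalFrame(origin=origin, ux=fx, uy=fy, uz=fz)


def flexion_angle(humerus: AnatomicalFrame, forearm: AnatomicalFrame) -> float:
    """Elbow flexion in degrees: the angle between the two frames' y-axes."""
    return angle_between_unit_vectors(humerus.uy, forearm.uy)


@dataclass
class AngleSeries:
    """Flexion-angle time series: timestamps (s) and angles (deg, [0, 180])."""

    t: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float).reshape(-1)
        self.phi = np.asarray(self.phi, dtype=float).reshape(-1)
        if self.t.size != self.phi.size:
            raise ValidationError("t and phi must have equal length")
        if self.phi.size and (
            not np.all(np.isfinite(self.phi))
            or np.any(self.phi < -1e-9)
            or np.any(self.phi > 180.0 + 1e-9)
        ):
            raise ValidationError("flexion angles must be finite and within [0, 180] degrees")
        np.clip(self.phi, 0.0, 180.0, out=self.phi)

    def __len__(self) -> int:
        return self.t.size


def _frame_axes_batch(p_g, p_m, p_l, p_r, p_u):
    """Vectorized y-axes of both frames plus a degenerate-geometry mask.

    Inputs are (n, 3) landmark trajectories; returns ``(uy, fy, ok)``.
    """
    p_lm2 = 0.5 * (p_m + p_l)
    p_ru2 = 0.5 * (p_u + p_r)

    area_h = 0.5 * np.linalg.norm(np.cross(p_m - p_g, p_l - p_g), axis=1)
    area_f = 0.5 * np.linalg.norm(np.cross(p_r - p_lm2, p_u - p_lm2), axis=1)
    ok = (area_h > MIN_TRIANGLE_AREA_MM2) & (area_f > MIN_TRIANGLE_AREA_MM2)

    def unit_rows(v):
        n = np.linalg.norm(v, axis=1, keepdims=True)
        small = n[:, 0] < 1e-12
        n[small] = 1.0
        return v / n, small

    uz, bad1 = unit_rows(p_g - p_lm2)
    uy, bad2 = unit_rows(np.cross(p_l - p_lm2, uz))
    fz, bad3 = unit_rows(p_lm2 - p_ru2)
    fy, bad4 = unit_rows(np.cross(p_r - p_ru2, fz))
    ok &= ~(bad1 | bad2 | bad3 | bad4)
    return uy, fy, ok


def angle_timeseries(
    humerus_stream: PoseStream,
    forearm_stream: PoseStream,
    registry: LandmarkRegistry,
) -> AngleSeries:
    """Flexion angle at every aligned sample of the two bone-fixed streams.

    Per sample: reconstruct the five landmarks from the registry and the
    current sensor poses, build both anatomical frames, and take the angle
    between their y-axes. Samples with degenerate landmark geometry are
    excluded and logged. Streams are paired by nearest timestamp (maximum
    gap: half a sample period).
    """
    if len(humerus_stream) == 0 or len(forearm_stream) == 0:
        return AngleSeries(t=np.array([]), phi=np.array([]))
    idx_h, idx_f = align_streams(humerus_stream, forearm_stream)

    rot_h = humerus_stream.rotations()[idx_h]
    pos_h = humerus_stream.positions[idx_h]
    rot_f = forearm_stream.rotations()[idx_f]
    pos_f = forearm_stream.positions[idx_f]

    def world(lm: Landmark) -> np.ndarray:
        entry = registry[lm]
        if entry.host_sensor == HUMERUS:
            return rot_h.apply(entry.local) + pos_h
        return rot_f.apply(entry.local) + pos_f

    uy, fy, ok = _frame_axes_batch(
        world(Landmark.GREATER_TUBERCLE),
        world(Landmark.MEDIAL_EPICONDYLE),
        world(Landmark.LATERAL_EPICONDYLE),
        world(Landmark.RADIAL_STYLOID),
        world(Landmark.ULNAR_STYLOID),
    )
    n_bad = int(np.count_nonzero(~ok))
    if n_bad:
        logger.warning("excluded %d sample(s) with degenerate landmark geometry", n_bad)

    cross = np.cross(uy[ok], fy[ok])
    dot = np.einsum("ij,ij->i", uy[ok], fy[ok])
    phi = np.degrees(np.arctan2(np.linalg.norm(cross, axis=1), dot))
    return AngleSeries(t=humerus_stream.t[idx_h][ok], phi=phi)
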