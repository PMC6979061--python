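"""Exact 3D vector and rotation primitives.

All public functions exchange angles in **degrees** and positions in
millimetres.  Rotations are right-handed: a positive angle turns
counter-clockwise when looking down the axis direction (i.e. with the axis
pointing at the viewer).  Vectors are plain length-3 ``numpy`` arrays; the
small container classes below only add the invariants the rest of the
package relies on (unit directions, orthonormal right-handed frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "DegenerateProjectionError",
    "DegenerateFrameError",
    "Axis",
    "Plane",
    "Frame",
    "as_vec3",
    "unit",
    "rotation_matrix",
    "rotate_about_axis",
    "project_vector_onto_plane",
    "signed_angle_in_plane",
    "angle_between",
    "build_right_handed_frame",
]

#: absolute tolerance for unit-norm / orthogonality invariants
UNIT_TOL = 1e-9
#: inputs within this distance of unit norm are silently normalised
NORMALISE_TOL = 1e-6


class GeometryError(ValueError):
    """Base class for geometric precondition failures."""


class DegenerateProjectionError(GeometryError):
    """A vector projected onto a plane vanished (vector ∥ plane normal)."""


class DegenerateFrameError(GeometryError):
    """Frame construction failed (axis hint parallel to the primary axis)."""


def as_vec3(v) -> np.ndarray:
    """Coerce *v* to a finite float64 array of shape (3,)."""
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise GeometryError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise GeometryError(f"non-finite vector components: {a}")
    return a


def unit(v) -> np.ndarray:
    """Return *v* normalised to unit length.

    Raises
    ------
    GeometryError
        If ``|v|`` is numerically zero.
    """
    a = as_vec3(v)
    n = np.linalg.norm(a)
    if n < UNIT_TOL:
        raise GeometryError("cannot normalise a zero vector")
    return a / n


def _checked_unit(v, what: str) -> np.ndarray:
    """Validate that *v* is unit within NORMALISE_TOL, then renormalise."""
    a = as_vec3(v)
    n = np.linalg.norm(a)
    if abs(n - 1.0) > NORMALISE_TOL:
        raise GeometryError(f"{what} must be a unit vector (|v| = {n:.9f})")
    return a / n


@dataclass(frozen=True)
class Axis:
    """An oriented line: a point on the line and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", as_vec3(self.point))
        object.__setattr__(
            self, "direction", _checked_unit(self.direction, "Axis.direction")
        )


@dataclass(frozen=True)
class Plane:
    """A plane given by one of its points and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", as_vec3(self.point))
        object.__setattr__(
            self, "normal", _checked_unit(self.normal, "Plane.normal")
        )

    def signed_distance(self, p) -> float:
        """Signed distance of *p* from the plane, positive along the normal."""
        return float(np.dot(as_vec3(p) - self.point, self.normal))


@dataclass(frozen=True)
class Frame:
    """A right-handed orthonormal coordinate frame with an origin.

    Satisfies ``x = y × z`` (equivalently ``x · (y × z) = +1``) and pairwise
    orthogonality to within 1e-9.
    """

    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", as_vec3(self.origin))
        for name in ("x", "y", "z"):
            object.__setattr__(
                self, name, _checked_unit(getattr(self, name), f"Frame.{name}")
            )
        for a, b in (("x", "y"), ("y", "z"), ("x", "z")):
            d = abs(np.dot(getattr(self, a), getattr(self, b)))
            if d > NORMALISE_TOL:
                raise DegenerateFrameError(
                    f"Frame axes {a} and {b} not orthogonal (dot = {d:.3e})"
                )
        if np.linalg.norm(np.cross(self.y, self.z) - self.x) > NORMALISE_TOL:
            raise DegenerateFrameError("Frame is not right-handed (x != y × z)")

    def to_dict(self) -> dict:
        """JSON-serialisable representation (for debugging dumps)."""
        return {
            "origin": self.origin.tolist(),
            "x": self.x.tolist(),
            "y": self.y.tolist(),
            "z": self.z.tolist(),
        }


def rotation_matrix(direction, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix for a right-handed turn about *direction*."""
    d = _checked_unit(direction, "rotation axis direction")
    t = np.radians(angle_deg)
    K = np.array(
        [
            [0.0, -d[2], d[1]],
            [d[2], 0.0, -d[0]],
            [-d[1], d[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(t) * K + (1.0 - np.cos(t)) * (K @ K)


def rotate_about_axis(p, axis: Axis, angle_deg: float) -> np.ndarray:
    """Rotate point *p* about an arbitrary axis.

    The rotation is right-handed by ``angle_deg`` degrees about the line
    through ``axis.point`` along ``axis.direction``.  Distances to the axis
    are preserved exactly (rigid motion).
    """
    R = rotation_matrix(axis.direction, angle_deg)
    return axis.point + R @ (as_vec3(p) - axis.point)


def rotate_vector(v, direction, angle_deg: float) -> np.ndarray:
    """Rotate a free vector (no translation) about *direction*."""
    return rotation_matrix(direction, angle_deg) @ as_vec3(v)


def project_vector_onto_plane(v, normal) -> np.ndarray:
    """Orthogonal projection of *v* onto the plane with unit *normal*.

    Returns ``v − (v·n)n``.  Raises :class:`DegenerateProjectionError` when
    *v* is (numerically) parallel to the normal, i.e. the projection
    vanishes.
    """
    n = _checked_unit(normal, "plane normal")
    a = as_vec3(v)
    proj = a - np.dot(a, n) * n
    if np.linalg.norm(proj) < UNIT_TOL:
        raise DegenerateProjectionError(
            "vector is parallel to the plane normal; projection is degenerate"
        )
    return proj


def signed_angle_in_plane(u, v, normal) -> float:
    """Signed angle (degrees, in (−180, 180]) from *u* to *v* about *normal*.

    Both vectors are first projected onto the plane perpendicular to
    *normal*; the angle is positive for a right-handed turn about the
    normal.
    """
    n = _checked_unit(normal, "plane normal")
    up = project_vector_onto_plane(u, n)
    vp = project_vector_onto_plane(v, n)
    ang = np.degrees(np.arctan2(np.dot(np.cross(up, vp), n), np.dot(up, vp)))
    # map -180 exactly onto +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def angle_between(u, v) -> float:
    """Unsigned angle between two vectors in degrees, in [0, 180]."""
    uu = unit(u)
    vv = unit(v)
    # atan2 form is well-conditioned near 0 and 180
    return float(
        np.degrees(np.arctan2(np.linalg.norm(np.cross(uu, vv)), np.dot(uu, vv)))
    )


def build_right_handed_frame(origin, y_dir, z_hint) -> Frame:
    """Construct a right-handed frame from a primary axis and a hint.

    ``y`` is the normalised *y_dir*; ``z`` is the normalised projection of
    *z_hint* onto the plane perpendicular to ``y`` (Gram–Schmidt step);
    ``x = y × z``.  Raises :class:`DegenerateFrameError` if *z_hint* is
    parallel to *y_dir*.
    """
    y = unit(y_dir)
    try:
        z = unit(project_vector_onto_plane(z_hint, y))
    except DegenerateProjectionError as exc:
        raise DegenerateFrameError(
            "z_hint is parallel to y_dir; frame is degenerate"
        ) from exc
    x = np.cross(y, z)
    return Frame(origin=as_vec3(origin), x=x, y=y, z=z)
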