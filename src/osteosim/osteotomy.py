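"""Osteotomy planes, the surgical reference frame, and fragment rotation.

The reference coordinate system at the osteotomy level follows the
intraoperative orientation cues: its origin is the shaft centre at the cut
level, its ``y`` axis is the femoral mechanical axis (pointing proximal),
and its ``z`` axis points medially along the projection of the femoral neck
axis (subtrochanteric cuts, reflecting the lateral approach) or of the
posterior condylar tangent (supracondylar cuts).  ``x = y × z`` points
anteriorly.

The intended ("baseline") osteotomy plane is perpendicular to the
mechanical femoral axis.  Mal-angulated planes tilt the baseline normal
about the frame's ``x`` axis (frontal-plane angulation) or ``z`` axis
(sagittal-plane angulation).  The simulated rotation then turns the distal
fragment *on the cut surface*, i.e. about the (possibly tilted) plane
normal through the frame origin.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import (
    Axis,
    Frame,
    Plane,
    build_right_handed_frame,
    rotate_vector,
    rotation_matrix,
    unit,
)
from .leg import MEDIAL, LegLandmarks, POINT_FIELDS, shaft_point_at_level, split_fragments

__all__ = [
    "GRID_MAGNITUDES_DEG",
    "GRID_ROTATIONS_DEG",
    "PlaneAngulation",
    "RotationSpec",
    "build_osteotomy_frame",
    "make_baseline_plane",
    "tilt_plane",
    "apply_rotational_osteotomy",
]

#: mal-angulation magnitudes of the factorial study design (degrees)
GRID_MAGNITUDES_DEG = (5.0, 10.0, 15.0, 20.0, 30.0)
#: fragment rotation magnitudes of the factorial study design (degrees)
GRID_ROTATIONS_DEG = (5.0, 10.0, 15.0, 20.0, 30.0)

_SITES = ("subtrochanteric", "supracondylar")


@dataclass(frozen=True)
class PlaneAngulation:
    """A mal-angulation of the osteotomy plane.

    ``plane``: 'frontal' (tilt about the frame x axis) or 'sagittal' (tilt
    about the frame z axis).  ``direction``: 'plus' or 'minus', the sign of
    the right-handed tilt about that frame axis; 'plus' corresponds to the
    counter-clockwise direction when looking down the tilt axis.
    """

    plane: str
    magnitude_deg: float
    direction: str = "plus"

    def __post_init__(self):
        if self.plane not in ("frontal", "sagittal"):
            raise ValueError(f"unknown angulation plane: {self.plane!r}")
        if self.direction not in ("plus", "minus"):
            raise ValueError(f"unknown angulation direction: {self.direction!r}")
        if self.magnitude_deg < 0:
            raise ValueError("angulation magnitude must be non-negative")

    @property
    def signed_magnitude_deg(self) -> float:
        return self.magnitude_deg if self.direction == "plus" else -self.magnitude_deg


@dataclass(frozen=True)
class RotationSpec:
    """Magnitude and sense of the fragment rotation.

    ``sense``: 'external' turns the distal fragment's anterior aspect
    laterally (right leg), 'internal' medially.
    """

    theta_deg: float
    sense: str = "external"

    def __post_init__(self):
        if self.sense not in ("external", "internal"):
            raise ValueError(f"unknown rotation sense: {self.sense!r}")
        if self.theta_deg < 0:
            raise ValueError("rotation magnitude must be non-negative")

    @property
    def signed_theta_deg(self) -> float:
        """Right-handed angle about the proximally oriented plane normal."""
        return self.theta_deg if self.sense == "external" else -self.theta_deg


def build_osteotomy_frame(
    lm: LegLandmarks, site: str, level_offset_mm: float
) -> Frame:
    """Reference frame at the osteotomy level.

    Origin: shaft centre at the cut level.  y: mechanical axis, proximal.
    z: in-plane projection of the neck axis (subtrochanteric) or posterior
    condylar tangent (supracondylar), flipped if needed to point medially.
    x = y × z (anterior).
    """
    if site not in _SITES:
        raise ValueError(f"unknown osteotomy site: {site!r}")
    origin = shaft_point_at_level(lm, site, level_offset_mm)
    y_dir = lm.hip_center - lm.knee_center
    if site == "subtrochanteric":
        hint = lm.neck_axis
    else:
        hint = lm.posterior_condylar_tangent
    frame = build_right_handed_frame(origin, y_dir, hint)
    if np.dot(frame.z, MEDIAL) < 0:
        frame = build_right_handed_frame(origin, y_dir, -hint)
    return frame


def make_baseline_plane(frame: Frame) -> Plane:
    """Intended osteotomy plane: through the frame origin, perpendicular to
    the mechanical femoral axis."""
    return Plane(point=frame.origin, normal=frame.y)


def tilt_plane(frame: Frame, angulation: PlaneAngulation) -> Plane:
    """Mal-angulated osteotomy plane.

    Rotates the baseline normal (frame ``y``) about frame ``x`` for a
    frontal-plane angulation or about frame ``z`` for a sagittal-plane
    angulation, by the signed magnitude.  Zero magnitude returns the
    baseline plane.
    """
    if angulation.magnitude_deg == 0.0:
        return make_baseline_plane(frame)
    tilt_axis = frame.x if angulation.plane == "frontal" else frame.z
    normal = rotate_vector(frame.y, tilt_axis, angulation.signed_magnitude_deg)
    return Plane(point=frame.origin, normal=normal)


def apply_rotational_osteotomy(
    lm: LegLandmarks,
    plane: Plane,
    frame: Frame,
    rot: RotationSpec,
    rotation_axis: str = "plane_normal",
) -> LegLandmarks:
    """Rotate the distal fragment on the osteotomy plane.

    The rotation axis passes through the frame origin along the plane
    normal (oriented proximally); with ``rotation_axis='baseline_y'`` the
    untilted mechanical-axis direction is used instead (sensitivity
    check).  External rotation is a right-handed positive turn about the
    proximally oriented axis for a right leg: the distal fragment's
    anterior aspect moves laterally.  Proximal landmarks are unchanged; the
    returned model records the applied transform.
    """
    if rotation_axis not in ("plane_normal", "baseline_y"):
        raise ValueError(f"unknown rotation_axis mode: {rotation_axis!r}")
    assignment = split_fragments(lm, plane)  # raises InvalidPlaneError if bad

    direction = plane.normal if rotation_axis == "plane_normal" else frame.y
    # orient the axis proximally (towards the hip)
    if np.dot(direction, lm.hip_center - lm.knee_center) < 0:
        direction = -direction
    axis = Axis(point=frame.origin, direction=unit(direction))
    theta = rot.signed_theta_deg
    R = rotation_matrix(axis.direction, theta)

    def move(p):
        return axis.point + R @ (p - axis.point)

    kwargs = {}
    for name in POINT_FIELDS:
        pt = getattr(lm, name)
        kwargs[name] = move(pt) if name in assignment.distal else pt

    neck = lm.neck_axis
    if "hip_center" in assignment.distal:  # pragma: no cover - defensive
        neck = R @ neck

    poly = lm.shaft_polyline.copy()
    mask = assignment.polyline_distal
    poly[mask] = (poly[mask] - axis.point[None, :]) @ R.T + axis.point[None, :]

    record = {
        "kind": "rotational_osteotomy",
        "axis_point": axis.point.tolist(),
        "axis_direction": axis.direction.tolist(),
        "angle_deg": theta,
        "sense": rot.sense,
        "rotation_axis": rotation_axis,
    }
    return replace(
        lm,
        neck_axis=neck,
        shaft_polyline=poly,
        transforms=lm.transforms + (record,),
        **kwargs,
    )
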