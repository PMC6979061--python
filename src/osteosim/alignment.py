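"""AP-projected mechanical leg axis (hip–knee–ankle angle) measurement.

The frontal mechanical leg axis is the signed angle between the femoral
mechanical axis (hip centre → knee centre) and the tibial mechanical axis
(knee centre → ankle centre), both projected onto the frontal plane.
Positive values are valgus, negative varus (right leg).

Because the original description of the AP projection is under-specified,
two projection modes are provided:

``knee_anchored`` (default)
    The antero-posterior direction is rebuilt from the limb itself: the
    cross product of the limb's longitudinal direction (ankle → knee) with
    the posterior condylar tangent.  This emulates a patella-forward
    standing radiograph of the (possibly rotated) limb and makes the
    measurement exactly invariant to rigid transforms of the whole leg.

``global_fixed``
    The pre-operative anterior direction is used, either taken from a
    supplied pre-operative reference model or, by default, the canonical
    global anterior axis in which synthetic legs are generated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    Axis,
    Frame,
    Plane,
    rotate_about_axis,
    signed_angle_in_plane,
    unit,
)
from .leg import ANTERIOR, InvalidPlaneError, LegLandmarks, split_fragments

__all__ = [
    "PROJECTION_MODES",
    "AlignmentResult",
    "measure_projected_hka",
    "deviation_from_preop",
    "hip_center_locus",
]

PROJECTION_MODES = ("knee_anchored", "global_fixed")


@dataclass(frozen=True)
class AlignmentResult:
    """One frontal mechanical-axis measurement.

    ``hka_valgus_deg``: signed hip–knee–ankle angle (+ valgus, − varus).
    ``femoral_axis`` / ``tibial_axis``: unit 3D directions hip→knee and
    knee→ankle.  ``projection_normal``: the AP direction used for the
    frontal projection.  ``mode``: the projection mode that produced it.
    """

    hka_valgus_deg: float
    femoral_axis: np.ndarray
    tibial_axis: np.ndarray
    projection_normal: np.ndarray
    mode: str


def _limb_ap_normal(lm: LegLandmarks) -> np.ndarray:
    """Anterior direction of a patella-forward view of *lm*.

    Cross product of the limb's longitudinal direction (ankle → knee,
    pointing proximal) with the posterior condylar tangent (pointing
    medial); for the canonical pre-operative pose this is the global
    anterior axis.
    """
    vertical = unit(lm.knee_center - lm.ankle_center)
    return unit(np.cross(vertical, lm.posterior_condylar_tangent))


def measure_projected_hka(
    lm: LegLandmarks,
    mode: str = "knee_anchored",
    reference: LegLandmarks | None = None,
) -> AlignmentResult:
    """Measure the AP-projected mechanical leg axis of *lm*.

    Parameters
    ----------
    lm
        The (possibly osteotomised) landmark model.
    mode
        Projection mode, see module docstring.
    reference
        Pre-operative model supplying the AP direction in ``global_fixed``
        mode; ignored for ``knee_anchored``.
    """
    if mode not in PROJECTION_MODES:
        raise ValueError(f"unknown projection mode: {mode!r}")
    if mode == "knee_anchored":
        n_ap = _limb_ap_normal(lm)
    else:
        n_ap = _limb_ap_normal(reference) if reference is not None else ANTERIOR
    femoral = unit(lm.knee_center - lm.hip_center)
    tibial = unit(lm.ankle_center - lm.knee_center)
    # positive right-handed turn from the femoral-axis extension to the
    # tibial axis about the anterior normal = valgus for a right leg
    hka = signed_angle_in_plane(femoral, tibial, n_ap)
    return AlignmentResult(
        hka_valgus_deg=hka,
        femoral_axis=femoral,
        tibial_axis=tibial,
        projection_normal=n_ap,
        mode=mode,
    )


def deviation_from_preop(pre: AlignmentResult, post: AlignmentResult) -> float:
    """Absolute change of the signed HKA angle, in degrees (≥ 0)."""
    if pre.mode != post.mode:
        raise ValueError(
            f"projection mode mismatch: {pre.mode!r} vs {post.mode!r}"
        )
    return abs(post.hka_valgus_deg - pre.hka_valgus_deg)


def hip_center_locus(
    lm: LegLandmarks,
    plane: Plane,
    frame: Frame,
    thetas_deg,
    sense: str = "external",
):
    """Hip-centre trajectory relative to the distal fragment.

    For each rotation angle the hip centre is expressed in the
    distal-fragment frame (equivalently: the hip is counter-rotated about
    the osteotomy axis while the distal limb is held fixed).  All positions
    lie on one circle about the rotation axis; the AP-projected distance of
    each position from the pre-operative hip centre explains how the
    frontal axis deviation evolves with rotation.

    Returns a list of ``(theta_deg, hip_position, ap_distance_mm)`` tuples.
    """
    assignment = split_fragments(lm, plane)
    if "hip_center" not in assignment.proximal:
        raise InvalidPlaneError("hip centre must lie proximal to the plane")
    direction = plane.normal
    if np.dot(direction, lm.hip_center - lm.knee_center) < 0:
        direction = -direction
    axis = Axis(point=frame.origin, direction=direction)
    sign = 1.0 if sense == "external" else -1.0
    n_ap = _limb_ap_normal(lm)
    out = []
    for theta in thetas_deg:
        # distal fragment turns by +theta; relative hip motion is -theta
        hip_rel = rotate_about_axis(lm.hip_center, axis, -sign * float(theta))
        d = hip_rel - lm.hip_center
        d_frontal = d - np.dot(d, n_ap) * n_ap
        out.append((float(theta), hip_rel, float(np.linalg.norm(d_frontal))))
    return out
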