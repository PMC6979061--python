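"""Parametric landmark model of a right lower limb.

The simulation study needs a lower extremity only through a handful of
anatomical landmarks and axes: hip (femoral head) centre, knee centre
(intercondylar notch), ankle centre, lesser trochanter, femoral neck axis,
posterior and distal condylar tangents, and the bowed femoral shaft.  This
module generates such a landmark model deterministically from printed
clinical parameters (femoral torsion, antecurvatum, mLDFA, pre-operative
hip–knee–ankle angle) and provides the inverse measurements so that every
generated model can be validated by round-trip.

Global coordinate convention (right leg): the knee centre sits at the
origin; ``X`` points anteriorly, ``Y`` proximally, ``Z`` medially.  The
basis (X, Y, Z) is right-handed.

Sign conventions
----------------
* femoral torsion: positive = antetorsion (neck anterior to the posterior
  condylar plane), negative = retrotorsion;
* hip–knee–ankle (HKA) angle: positive = valgus, negative = varus;
* antecurvatum: anterior bow of the shaft, non-negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    GeometryError,
    Plane,
    angle_between,
    as_vec3,
    project_vector_onto_plane,
    rotate_vector,
    signed_angle_in_plane,
    unit,
)

__all__ = [
    "ANTERIOR",
    "PROXIMAL",
    "MEDIAL",
    "ConstructionError",
    "InvalidPlaneError",
    "LegParameters",
    "LegLandmarks",
    "FragmentAssignment",
    "MODEL_1",
    "MODEL_2",
    "generate_synthetic_leg",
    "measure_femoral_torsion",
    "measure_mldfa",
    "measure_antecurvatum",
    "shaft_point_at_level",
    "split_fragments",
    "mirror_landmarks",
    "jitter_landmarks",
    "landmarks_to_json",
    "landmarks_from_json",
]

ANTERIOR = np.array([1.0, 0.0, 0.0])
PROXIMAL = np.array([0.0, 1.0, 0.0])
MEDIAL = np.array([0.0, 0.0, 1.0])

#: AP offset of the posterior condylar tangent behind the knee centre (mm).
#: Only sets where the tangent line sits; all angle measurements use its
#: direction, so the value is not critical.
POSTERIOR_CONDYLE_OFFSET_MM = 25.0

#: number of vertices of the generated shaft polyline
SHAFT_POLYLINE_POINTS = 257

#: a circular arc's proximal/distal third-chord angle is 2/3 of its full
#: tangent-to-tangent turn, so the generator starts from a turn of 3/2 the
#: nominal antecurvatum and then solves the turn numerically so that the
#: thirds-chord measurement (which also involves a sagittal projection)
#: round-trips exactly
ARC_TURN_PER_ANTECURVATUM = 1.5

#: landmark point attributes, in a stable serialisation order
POINT_FIELDS = (
    "hip_center",
    "knee_center",
    "ankle_center",
    "lesser_trochanter",
    "posterior_condyle_medial",
    "posterior_condyle_lateral",
    "distal_condyle_medial",
    "distal_condyle_lateral",
)


class ConstructionError(ValueError):
    """The requested leg parameters are geometrically inconsistent."""


class InvalidPlaneError(ValueError):
    """An osteotomy plane does not separate the limb into two fragments."""


@dataclass(frozen=True)
class LegParameters:
    """Clinical parameters defining one synthetic right lower limb.

    Lengths are millimetres, angles degrees.  The four printed deformity
    parameters (torsion, antecurvatum, mLDFA, pre-op HKA) are mandatory;
    the remaining dimensions default to adult norms and mainly control the
    lever arms of the proximal femur (see the methods note).
    """

    femoral_torsion_deg: float
    antecurvatum_deg: float
    mldfa_deg: float
    preop_hka_valgus_deg: float
    femur_length_mm: float = 420.0
    tibia_length_mm: float = 380.0
    neck_length_mm: float = 50.0
    neck_shaft_angle_deg: float = 127.0
    head_to_lt_distance_mm: float = 60.0
    condylar_halfwidth_mm: float = 40.0
    side: str = "right"

    def __post_init__(self):
        if self.side != "right":
            raise ConstructionError("only right-sided models are generated")
        if not -30.0 <= self.femoral_torsion_deg <= 60.0:
            raise ConstructionError(
                f"femoral torsion {self.femoral_torsion_deg}° outside [-30, 60]"
            )
        if not 0.0 <= self.antecurvatum_deg <= 30.0:
            raise ConstructionError(
                f"antecurvatum {self.antecurvatum_deg}° outside [0, 30]"
            )
        if not 75.0 <= self.mldfa_deg <= 95.0:
            raise ConstructionError(f"mLDFA {self.mldfa_deg}° outside [75, 95]")
        if abs(self.preop_hka_valgus_deg) > 25.0:
            raise ConstructionError(
                f"pre-op HKA {self.preop_hka_valgus_deg}° outside ±25"
            )
        if not 95.0 < self.neck_shaft_angle_deg < 165.0:
            raise ConstructionError(
                f"neck-shaft angle {self.neck_shaft_angle_deg}° implausible"
            )
        for name in (
            "femur_length_mm",
            "tibia_length_mm",
            "neck_length_mm",
            "head_to_lt_distance_mm",
            "condylar_halfwidth_mm",
        ):
            if getattr(self, name) <= 0:
                raise ConstructionError(f"{name} must be positive")
        if self.head_to_lt_distance_mm <= self.neck_length_mm * 0.5:
            raise ConstructionError(
                "head-to-lesser-trochanter distance incompatible with neck length"
            )


#: the two study models, from the printed patient parameters
MODEL_1 = LegParameters(
    femoral_torsion_deg=42.0,
    antecurvatum_deg=8.0,
    mldfa_deg=85.0,
    preop_hka_valgus_deg=2.4,
)
MODEL_2 = LegParameters(
    femoral_torsion_deg=-6.0,
    antecurvatum_deg=14.0,
    mldfa_deg=86.0,
    preop_hka_valgus_deg=5.1,
)


@dataclass(frozen=True)
class LegLandmarks:
    """Named 3D landmarks of one right lower limb (millimetres).

    ``shaft_polyline`` is an (N, 3) array of points along the femoral
    anatomical axis, ordered proximal → distal, encoding the anterior bow.
    ``neck_axis`` is a unit direction from the neck base towards the
    femoral head centre; it belongs to the proximal fragment.
    ``transforms`` records rigid transforms applied by simulated
    osteotomies (most recent last).
    """

    hip_center: np.ndarray
    knee_center: np.ndarray
    ankle_center: np.ndarray
    lesser_trochanter: np.ndarray
    posterior_condyle_medial: np.ndarray
    posterior_condyle_lateral: np.ndarray
    distal_condyle_medial: np.ndarray
    distal_condyle_lateral: np.ndarray
    neck_axis: np.ndarray
    shaft_polyline: np.ndarray
    side: str = "right"
    transforms: tuple = ()

    def __post_init__(self):
        for name in POINT_FIELDS:
            object.__setattr__(self, name, as_vec3(getattr(self, name)))
        object.__setattr__(self, "neck_axis", unit(self.neck_axis))
        poly = np.asarray(self.shaft_polyline, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 3 or poly.shape[0] < 2:
            raise ConstructionError("shaft_polyline must be an (N>=2, 3) array")
        object.__setattr__(self, "shaft_polyline", poly)

    def points(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in POINT_FIELDS}

    @property
    def mechanical_axis_direction(self) -> np.ndarray:
        """Unit vector knee centre → hip centre (pointing proximal)."""
        return unit(self.hip_center - self.knee_center)

    @property
    def posterior_condylar_tangent(self) -> np.ndarray:
        """Unit direction of the posterior condylar tangent, pointing medial."""
        return unit(self.posterior_condyle_medial - self.posterior_condyle_lateral)


@dataclass(frozen=True)
class FragmentAssignment:
    """Partition of the landmarks by an osteotomy plane.

    ``polyline_distal`` is a boolean mask over shaft polyline vertices
    (True = distal side of the cut).
    """

    proximal: frozenset
    distal: frozenset
    polyline_distal: np.ndarray


def _arc_polyline(B, K, turn_deg, n=SHAFT_POLYLINE_POINTS):
    """Circular-arc polyline from *B* to *K* bulging anteriorly, with a
    tangent-to-tangent turn of *turn_deg* degrees."""
    chord = K - B
    C = np.linalg.norm(chord)
    d = chord / C
    if turn_deg == 0.0:
        t = np.linspace(0.0, 1.0, n)[:, None]
        return B[None, :] + t * chord[None, :]
    try:
        b = unit(project_vector_onto_plane(ANTERIOR, d))
    except GeometryError as exc:  # chord parallel to AP axis: not a femur
        raise ConstructionError("shaft chord is antero-posterior") from exc
    phi = np.radians(turn_deg)
    radius = C / (2.0 * np.sin(phi / 2.0))
    mid = 0.5 * (B + K)
    center = mid - b * radius * np.cos(phi / 2.0)
    psi = np.linspace(-phi / 2.0, phi / 2.0, n)
    return center[None, :] + radius * (
        np.cos(psi)[:, None] * b[None, :] + np.sin(psi)[:, None] * d[None, :]
    )


def _polyline_antecurvatum(poly: np.ndarray) -> float:
    """Thirds-chord antecurvatum of a shaft polyline (degrees).

    Sagittal-plane angle between the chord of the proximal third and the
    chord of the distal third.
    """
    if poly.shape[0] < 3:
        raise ConstructionError("shaft polyline needs at least 3 points")
    k = max(1, poly.shape[0] // 3)
    prox = project_vector_onto_plane(poly[k] - poly[0], MEDIAL)
    dist = project_vector_onto_plane(poly[-1] - poly[-1 - k], MEDIAL)
    return angle_between(prox, dist)


def _shaft_arc(proximal_pt, distal_pt, antecurvatum_deg, n=SHAFT_POLYLINE_POINTS):
    """Shaft polyline whose measured thirds-chord antecurvatum equals
    *antecurvatum_deg*.

    The measured angle of a circular arc is close to, but (because of the
    sagittal projection and the discrete thirds) not exactly, 2/3 of its
    turn; the turn is therefore solved by a fixed-point iteration so the
    measurement round-trips to machine precision.
    """
    B = as_vec3(proximal_pt)
    K = as_vec3(distal_pt)
    if np.linalg.norm(K - B) < 1e-6:
        raise ConstructionError("shaft chord has zero length")
    # below ~1e-6 deg the arc radius overflows the useful float range and
    # the bow is far beyond measurement resolution: treat as straight
    if antecurvatum_deg < 1e-6:
        return _arc_polyline(B, K, 0.0, n)
    turn = ARC_TURN_PER_ANTECURVATUM * antecurvatum_deg
    poly = _arc_polyline(B, K, turn, n)
    for _ in range(20):
        measured = _polyline_antecurvatum(poly)
        if abs(measured - antecurvatum_deg) < 1e-8:
            break
        turn *= antecurvatum_deg / measured
        poly = _arc_polyline(B, K, turn, n)
    else:  # pragma: no cover - the map is a near-linear contraction
        if abs(_polyline_antecurvatum(poly) - antecurvatum_deg) > 1e-4:
            raise ConstructionError(
                f"antecurvatum of {antecurvatum_deg}° did not converge"
            )
    return poly


def _locate_lesser_trochanter(polyline, hip, target_distance):
    """First point along the shaft whose distance from the hip centre
    reaches *target_distance* (linear interpolation between vertices)."""
    dists = np.linalg.norm(polyline - hip[None, :], axis=1)
    if dists[0] > target_distance:
        raise ConstructionError(
            "neck geometry places the proximal shaft farther from the head "
            "than the requested head-to-lesser-trochanter distance"
        )
    idx = np.nonzero(dists >= target_distance)[0]
    if idx.size == 0 or idx[0] > polyline.shape[0] // 2:
        raise ConstructionError(
            "lesser trochanter level not found on the proximal half of the shaft"
        )
    i = int(idx[0])
    d0, d1 = dists[i - 1], dists[i]
    w = 0.0 if d1 == d0 else (target_distance - d0) / (d1 - d0)
    return polyline[i - 1] + w * (polyline[i] - polyline[i - 1])


def generate_synthetic_leg(params: LegParameters) -> LegLandmarks:
    """Deterministically construct landmarks matching *params*.

    The knee centre sits at the origin, the tibial mechanical axis runs
    straight down the global vertical, and the femoral mechanical axis is
    tilted in the frontal plane by the pre-operative HKA angle (so that the
    AP-projected HKA of the generated leg equals ``preop_hka_valgus_deg``
    exactly).  The neck axis realises the requested torsion relative to the
    posterior condylar tangent and the requested neck-shaft elevation; the
    shaft polyline is anchored at the neck base and at the knee centre and
    bows anteriorly by the antecurvatum angle.
    """
    p = params
    knee = np.zeros(3)
    ankle = -p.tibia_length_mm * PROXIMAL

    # femoral mechanical axis: tilted in the frontal (Y–Z) plane so that the
    # hip sits lateral of the knee→ankle line for a valgus leg
    h = np.radians(p.preop_hka_valgus_deg)
    u_f = np.array([0.0, np.cos(h), -np.sin(h)])
    hip = knee + p.femur_length_mm * u_f

    # distal condylar tangent (knee joint line): rotate the mechanical axis
    # within the frontal plane so the *lateral* axis/joint-line angle is the
    # mLDFA
    j = rotate_vector(u_f, ANTERIOR, 180.0 - p.mldfa_deg)
    dc_med = knee + p.condylar_halfwidth_mm * j
    dc_lat = knee - p.condylar_halfwidth_mm * j

    # posterior condylar tangent: mediolateral line in the transverse plane
    pc_center = knee - POSTERIOR_CONDYLE_OFFSET_MM * ANTERIOR
    pc_med = pc_center + p.condylar_halfwidth_mm * MEDIAL
    pc_lat = pc_center - p.condylar_halfwidth_mm * MEDIAL

    # neck axis: start from the condylar tangent projected perpendicular to
    # the mechanical axis, twist by the torsion angle (anteriorly for
    # antetorsion), then elevate by the neck-shaft angle above the
    # transverse plane
    m = unit(project_vector_onto_plane(MEDIAL, u_f))
    m_t = rotate_vector(m, u_f, p.femoral_torsion_deg)
    gamma = np.radians(p.neck_shaft_angle_deg - 90.0)
    neck_axis = np.cos(gamma) * m_t + np.sin(gamma) * u_f

    neck_base = hip - p.neck_length_mm * neck_axis
    polyline = _shaft_arc(neck_base, knee, p.antecurvatum_deg)
    lt = _locate_lesser_trochanter(polyline, hip, p.head_to_lt_distance_mm)

    return LegLandmarks(
        hip_center=hip,
        knee_center=knee,
        ankle_center=ankle,
        lesser_trochanter=lt,
        posterior_condyle_medial=pc_med,
        posterior_condyle_lateral=pc_lat,
        distal_condyle_medial=dc_med,
        distal_condyle_lateral=dc_lat,
        neck_axis=neck_axis,
        shaft_polyline=polyline,
    )


def measure_femoral_torsion(lm: LegLandmarks) -> float:
    """Femoral torsion in degrees (antetorsion positive).

    Signed angle between the posterior condylar tangent and the neck axis,
    both projected onto the plane perpendicular to the femoral mechanical
    axis.  For a right leg, a neck pointing anterior to the condylar plane
    yields a positive angle.
    """
    mech = lm.mechanical_axis_direction
    return signed_angle_in_plane(lm.posterior_condylar_tangent, lm.neck_axis, mech)


def measure_mldfa(lm: LegLandmarks) -> float:
    """Mechanical lateral distal femoral angle (degrees).

    Frontal-plane angle between the femoral mechanical axis (pointing
    proximal) and the knee joint line (pointing lateral).
    """
    mech = project_vector_onto_plane(lm.mechanical_axis_direction, ANTERIOR)
    lateral_jl = project_vector_onto_plane(
        lm.distal_condyle_lateral - lm.distal_condyle_medial, ANTERIOR
    )
    return angle_between(mech, lateral_jl)


def measure_antecurvatum(lm: LegLandmarks) -> float:
    """Anterior bow of the femoral shaft (degrees).

    Sagittal-plane angle between the chord of the proximal third and the
    chord of the distal third of the shaft polyline.
    """
    return _polyline_antecurvatum(lm.shaft_polyline)


def _polyline_arclengths(poly: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at_arclength(poly: np.ndarray, s: float) -> np.ndarray:
    cum = _polyline_arclengths(poly)
    total = cum[-1]
    if s < -1e-9 or s > total + 1e-9:
        raise ConstructionError(
            f"arc length {s:.1f} mm outside shaft span [0, {total:.1f}] mm"
        )
    s = min(max(s, 0.0), total)
    i = int(np.searchsorted(cum, s, side="right"))
    i = min(max(i, 1), poly.shape[0] - 1)
    w = (s - cum[i - 1]) / max(cum[i] - cum[i - 1], 1e-12)
    return poly[i - 1] + w * (poly[i] - poly[i - 1])


def shaft_point_at_level(lm: LegLandmarks, site: str, offset_mm: float) -> np.ndarray:
    """Shaft centre point at an osteotomy level.

    ``site='subtrochanteric'``: arc length *offset_mm* distal to the lesser
    trochanter level.  ``site='supracondylar'``: arc length *offset_mm*
    proximal to the distal condylar level (the distal end of the shaft).
    """
    poly = lm.shaft_polyline
    cum = _polyline_arclengths(poly)
    if site == "subtrochanteric":
        # arc length of the lesser-trochanter level: orthogonal projection of
        # the LT landmark onto the polyline (exact per segment)
        a = poly[:-1]
        seg = np.diff(poly, axis=0)
        seg_len2 = np.maximum(np.einsum("ij,ij->i", seg, seg), 1e-12)
        t = np.clip(
            np.einsum("ij,ij->i", lm.lesser_trochanter[None, :] - a, seg) / seg_len2,
            0.0,
            1.0,
        )
        foot = a + t[:, None] * seg
        i = int(np.argmin(np.linalg.norm(foot - lm.lesser_trochanter[None, :], axis=1)))
        s_lt = cum[i] + t[i] * np.sqrt(seg_len2[i])
        return _point_at_arclength(poly, s_lt + offset_mm)
    if site == "supracondylar":
        return _point_at_arclength(poly, cum[-1] - offset_mm)
    raise ValueError(f"unknown osteotomy site: {site!r}")


def split_fragments(lm: LegLandmarks, plane: Plane) -> FragmentAssignment:
    """Partition landmarks into proximal and distal fragments by *plane*.

    The plane normal is oriented towards the hip; landmarks on the hip side
    are proximal.  Shaft polyline vertices are split individually; every
    other landmark must clear the plane by more than 1e-6 mm.
    """
    d_hip = plane.signed_distance(lm.hip_center)
    d_ankle = plane.signed_distance(lm.ankle_center)
    if d_hip * d_ankle >= 0:
        raise InvalidPlaneError(
            "plane does not separate the hip from the ankle "
            f"(signed distances {d_hip:.2f} / {d_ankle:.2f} mm)"
        )
    toward_hip = 1.0 if d_hip > 0 else -1.0
    proximal, distal = set(), set()
    for name, pt in lm.points().items():
        d = plane.signed_distance(pt) * toward_hip
        if abs(d) <= 1e-6:
            raise InvalidPlaneError(f"landmark {name} lies on the osteotomy plane")
        (proximal if d > 0 else distal).add(name)
    poly_d = (
        (lm.shaft_polyline - plane.point[None, :]) @ plane.normal
    ) * toward_hip
    return FragmentAssignment(
        proximal=frozenset(proximal),
        distal=frozenset(distal),
        polyline_distal=poly_d <= 0,
    )


def mirror_landmarks(lm: LegLandmarks) -> LegLandmarks:
    """Mirror the limb across the sagittal midplane (medial → lateral).

    Measuring a mirrored limb with the right-leg conventions flips the sign
    of torsion and HKA (useful as a symmetry check).
    """
    flip = np.array([1.0, 1.0, -1.0])
    kwargs = {name: getattr(lm, name) * flip for name in POINT_FIELDS}
    return LegLandmarks(
        neck_axis=lm.neck_axis * flip,
        shaft_polyline=lm.shaft_polyline * flip[None, :],
        side=lm.side,
        transforms=lm.transforms,
        **kwargs,
    )


def jitter_landmarks(lm: LegLandmarks, sigma_mm: float, seed: int) -> LegLandmarks:
    """Gaussian positional jitter on all landmarks (robustness testing only).

    Disabled by default throughout the package; the study grid is fully
    deterministic.
    """
    rng = np.random.default_rng(seed)
    kwargs = {
        name: getattr(lm, name) + rng.normal(0.0, sigma_mm, 3)
        for name in POINT_FIELDS
    }
    poly = lm.shaft_polyline + rng.normal(0.0, sigma_mm, lm.shaft_polyline.shape)
    return LegLandmarks(
        neck_axis=lm.neck_axis,
        shaft_polyline=poly,
        side=lm.side,
        transforms=lm.transforms,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# serialisation


def landmarks_to_json(lm: LegLandmarks) -> str:
    """Serialise landmarks to the documented JSON schema (mm)."""
    doc = {
        "schema": "osteosim-landmarks-v1",
        "side": lm.side,
        "points": {name: getattr(lm, name).tolist() for name in POINT_FIELDS},
        "neck_axis": lm.neck_axis.tolist(),
        "shaft_polyline": lm.shaft_polyline.tolist(),
    }
    return json.dumps(doc, indent=2)


def landmarks_from_json(text: str) -> LegLandmarks:
    """Load landmarks from the JSON schema written by :func:`landmarks_to_json`."""
    doc = json.loads(text)
    if doc.get("schema") != "osteosim-landmarks-v1":
        raise ValueError("not an osteosim landmark document")
    return LegLandmarks(
        neck_axis=doc["neck_axis"],
        shaft_polyline=np.asarray(doc["shaft_polyline"], dtype=float),
        side=doc.get("side", "right"),
        **{name: doc["points"][name] for name in POINT_FIELDS},
    )


def landmarks_from_mesh(mesh_path, annotation_path) -> LegLandmarks:
    """Build landmarks from a surface mesh plus a landmark annotation file.

    The mesh (STL/PLY, read with :mod:`trimesh`) is used only to sanity-check
    that annotated points lie near the surface; all computations downstream
    use the annotated landmarks, which follow the same JSON schema as
    :func:`landmarks_to_json`.
    """
    import trimesh  # optional dependency

    with open(annotation_path) as fh:
        lm = landmarks_from_json(fh.read())
    mesh = trimesh.load(mesh_path, force="mesh")
    pts = np.array([getattr(lm, name) for name in POINT_FIELDS])
    _, dist, _ = trimesh.proximity.closest_point(mesh, pts)
    if np.max(dist) > 25.0:
        raise ValueError(
            "annotated landmarks lie far from the mesh surface "
            f"(max distance {np.max(dist):.1f} mm)"
        )
    return lm
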