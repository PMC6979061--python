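"""Walk through one mal-angulated rotational osteotomy.

Supracondylar cut on the antetorsion model, tilted 30 deg in the sagittal
plane, followed by 30 deg of external rotation of the distal fragment on
the cut surface.  The printed deviation is the change of the AP-projected
mechanical leg axis caused solely by the mal-angulation: on the baseline
(perpendicular) plane the same rotation leaves the axis almost unchanged.
"""

from osteosim import (
    MODEL_1,
    PlaneAngulation,
    RotationSpec,
    apply_rotational_osteotomy,
    build_osteotomy_frame,
    deviation_from_preop,
    generate_synthetic_leg,
    make_baseline_plane,
    measure_projected_hka,
    tilt_plane,
)

lm = generate_synthetic_leg(MODEL_1)
pre = measure_projected_hka(lm)
print(f"pre-operative HKA: {pre.hka_valgus_deg:+.2f} deg (valgus positive)")

frame = build_osteotomy_frame(lm, "supracondylar", 60.0)
print(f"osteotomy level (shaft centre): {frame.origin.round(1)} mm")

for label, plane in (
    ("baseline (perpendicular)", make_baseline_plane(frame)),
    ("sagittal mal-angulation +30 deg", tilt_plane(frame, PlaneAngulation("sagittal", 30.0))),
):
    rotated = apply_rotational_osteotomy(lm, plane, frame, RotationSpec(30.0, "external"))
    post = measure_projected_hka(rotated)
    dev = deviation_from_preop(pre, post)
    print(f"{label}: post-op HKA {post.hka_valgus_deg:+.2f} deg, "
          f"deviation {dev:.2f} deg")
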