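"""Trace the hip-centre circle behind the non-monotonic frontal case.

For a subtrochanteric osteotomy with a counter-clockwise 30-deg frontal
tilt on the retrotorsion model, the hip centre (expressed relative to the
distal fragment) travels on a circle about the rotation axis.  Its
mediolateral excursion - the component that drives varus/valgus - peaks
before 30 deg of rotation and then shrinks again, so the frontal axis
deviation decreases between 20 and 30 deg of rotation.

If matplotlib is available a frontal-view figure is saved to
``results/hip_center_locus.png``.
"""

import numpy as np

from osteosim import (
    MODEL_2,
    PlaneAngulation,
    build_osteotomy_frame,
    generate_synthetic_leg,
    hip_center_locus,
    tilt_plane,
)

lm = generate_synthetic_leg(MODEL_2)
frame = build_osteotomy_frame(lm, "subtrochanteric", 40.0)
plane = tilt_plane(frame, PlaneAngulation("frontal", 30.0, "minus"))

thetas = np.arange(0.0, 31.0, 2.5)
locus = hip_center_locus(lm, plane, frame, thetas, sense="internal")

print("rotation  mediolateral offset  frontal-plane distance")
for theta, pos, ap_dist in locus:
    ml = (pos - lm.hip_center)[2]
    print(f"  {theta:5.1f} deg   {ml:+7.2f} mm            {ap_dist:6.2f} mm")

try:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    pts = np.array([pos for _, pos, _ in locus])
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(pts[:, 2], pts[:, 1], "o-", color="tab:red", label="hip centre per rotation")
    ax.plot(lm.hip_center[2], lm.hip_center[1], "s", color="tab:green",
            label="pre-operative hip centre")
    ax.set_xlabel("medial (mm)")
    ax.set_ylabel("proximal (mm)")
    ax.set_title("Frontal view of the hip-centre locus")
    ax.legend()
    ax.set_aspect("equal")
    out = Path("results/hip_center_locus.png")
    out.parent.mkdir(exist_ok=True)
    fig.savefig(out, dpi=120, bbox_inches="tight")
    print(f"figure written to {out}")
except ImportError:
    print("matplotlib not installed; skipping the figure")
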