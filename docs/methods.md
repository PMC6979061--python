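# Methods

## Scope and approach

`osteosim` reproduces a computer-simulation experiment: cut a femur with a
baseline or mal-angulated osteotomy plane, rotate the distal fragment on
the cut surface, and measure the change of the AP-projected mechanical leg
axis (HKA).  The original experiment used CT-derived surface models of two
patients; those surfaces are not published, and every quantity in the
experiment depends only on axes and centres, so the package replaces the
surfaces with deterministic landmark models built from the printed
clinical parameters.  Surface meshes can still be ingested through a
landmark annotation file (`osteosim.leg.landmarks_from_mesh`), in which
case the mesh is used only for sanity checks.

All angles cross module boundaries in degrees; positions are millimetres.
Rotations are right-handed.  The global frame of a generated right leg is
X = anterior, Y = proximal, Z = medial, knee centre at the origin.

## Synthetic leg construction

Given torsion `t`, antecurvatum `a`, mLDFA `m`, pre-operative HKA `h` and
the dimensional parameters, the generator places:

- tibial mechanical axis straight down the global vertical
  (ankle = −L_tibia·Y);
- femoral mechanical axis u tilted by `h` in the frontal plane so the hip
  lies lateral of the knee–ankle line for valgus `h > 0` (the measured HKA
  is then `h` exactly);
- distal condylar tangent (joint line) in the frontal plane, rotated so the
  lateral axis/joint-line angle is `m`;
- posterior condylar tangent mediolateral, 25 mm posterior of the knee;
- neck axis: the condylar tangent projected perpendicular to u, twisted
  about u by `t` (anterior for antetorsion), then elevated by
  (neck-shaft angle − 90°) out of the transverse plane;
- shaft polyline: a circular arc from the neck base (hip − neck_length ·
  neck_axis) to the knee centre, bulging anteriorly.  The thirds-chord
  antecurvatum measurement of a circular arc is ≈ 2/3 of its
  tangent-to-tangent turn (plus a small sagittal-projection correction),
  so the turn is solved by a fixed-point iteration until the measurement
  returns `a` to 1e-8°.  Antecurvatum below 1e-6° is generated as a
  straight polyline (the arc radius would overflow useful float range);
- lesser trochanter: the first shaft point whose distance from the hip
  centre equals the head-to-LT parameter.

Everything is deterministic; `jitter_landmarks` adds seeded Gaussian noise
for robustness experiments and is off everywhere by default.

### Dimensional defaults

The printed parameters fix the deformity but not the bone dimensions.
Defaults are adult norms, all overridable per model: femur 420 mm, tibia
380 mm, neck length 50 mm, neck-shaft angle 127°, head-to-LT distance
60 mm, condylar halfwidth 40 mm.  Supracondylar results are almost
insensitive to these (the rotation axis passes close to the mechanical
axis and the hip lever is ~0.85 of the femur regardless); subtrochanteric
results scale nearly linearly with the hip-to-plane lever
(head-to-LT + level offset) and are additionally modulated by the
neck-projected frame (below), so their absolute magnitudes carry the
uncertainty of these unpublished dimensions.

## Osteotomy frames, planes, rotation

The reference frame at the cut level has its origin at the shaft centre
(arc length 45/40 mm distal to the LT level for subtrochanteric cuts,
60/65 mm proximal to the condylar level for supracondylar cuts), y along
the mechanical axis (proximal), and z the in-plane projection of the
femoral neck axis (subtrochanteric — mirroring the lateral surgical
approach) or of the posterior condylar tangent (supracondylar), pointing
medial; x = y × z.  A consequence worth noting: for a 42°-antetorted
femur the subtrochanteric frame is twisted 42° about the mechanical axis
relative to the patient's frontal/sagittal planes, so "frontal" and
"sagittal" tilts at that site are nearly equally effective
(sin 42° ≈ cos 42°), which compresses the sagittal-vs-frontal contrast of
the subtrochanteric cells relative to the supracondylar ones.

Mal-angulation rotates the baseline normal (y) about x (frontal) or z
(sagittal) by a signed magnitude; "clockwise/counter-clockwise" map to the
right-handed minus/plus senses (table cells pool both directions, so the
labelling does not affect any pooled result).  The fragment rotation turns
every distal landmark rigidly about the (possibly tilted) plane normal
through the frame origin — the fragment slides on the cut surface.  A
configuration flag (`rotation_axis="baseline_y"`) instead rotates about
the untilted mechanical axis for sensitivity comparisons.  External
rotation is the positive right-handed turn about the proximally oriented
normal (the distal fragment's anterior aspect moves laterally on a right
leg).

## HKA measurement

Femoral axis hip→knee and tibial axis knee→ankle are projected onto the
frontal plane of an AP direction n and the signed angle between them is
the HKA (valgus positive, by a cross-product convention stated for the
right side; left legs should be mirrored first).  Two choices of n are
implemented because the original measurement is under-specified:

- `knee_anchored` (default): n = (limb longitudinal direction) × (posterior
  condylar tangent), both taken from the *current* (possibly rotated)
  landmarks.  This emulates a patella-forward standing radiograph taken
  after the osteotomy and is exactly invariant to rigid transforms of the
  whole leg.  It reproduces the near-invariance of baseline-plane
  rotations.  (The limb's own longitudinal direction is used as the
  "vertical"; a laboratory-fixed vertical would break rigid-transform
  invariance.)
- `global_fixed`: n is the pre-operative anterior direction (from a
  reference model, or the canonical global X).  Retained for comparison;
  baseline rotations show larger apparent changes here because the rotated
  distal limb is not re-oriented to face the viewer.

Deviation is the absolute difference of signed HKA values, which lets
opposite tilt directions and both models pool into non-negative cell
means.

`hip_center_locus` expresses the hip centre in the distal-fragment frame
for a sweep of rotation angles; all positions lie on a circle about the
rotation axis.  Its mediolateral component explains the one documented
non-monotonic case: for the retrotorsion model with a counter-clockwise
frontal subtrochanteric tilt, the excursion peaks near 15° of rotation and
returns toward zero at 30°, so the deviation at 30° is smaller than at
20°.

## Study grid and summaries

Defaults reproduce the published design exactly: per model and site, one
baseline plane plus 2 tilt planes × 5 magnitudes × 2 directions, each with
5 rotations — 20 baseline runs, 80 mal-angulated planes, 400 mal-angulated
runs, completing in about a second.  Cells pool n = 4 runs (2 models × 2
directions) with the sample (n−1) standard deviation; the clinical
relevance flag is mean + SD strictly greater than 2°, the accuracy bound
commonly quoted for osteotomy corrections.  Outputs (`records.csv`,
`summary_long.csv`, per-site wide tables) are byte-reproducible; the wide
tables format cells as `mean +/- sd` with `*` marking relevant cells.

## Numerical choices

- Unit/orthogonality invariants at 1e-9; inputs within 1e-6 of unit norm
  are normalised rather than rejected.
- Signed angles via `atan2(‖u×v‖-type numerators, u·v)`, well-conditioned
  near 0° and 180°; range (−180°, 180°].
- Shaft polyline: 257 vertices (~1.5 mm spacing); level points by linear
  arc-length interpolation; the LT level by orthogonal projection onto the
  polyline.
- Fragment splitting requires every named landmark to clear the plane by
  more than 1e-6 mm (polyline vertices are split per side) and the plane to
  separate hip from ankle.

## What the synthetic models do and do not show

The generator reproduces the printed deformity parameters exactly and the
study's structural and qualitative findings (baseline near-invariance,
sagittal > frontal vulnerability, supracondylar > subtrochanteric,
monotone growth with tilt and rotation, the counter-clockwise frontal
exception).  Supracondylar cell magnitudes additionally match the
published values closely because they are dominated by the
lever-and-rotation geometry that the printed parameters pin down.
Subtrochanteric magnitudes are reproduced at roughly three quarters of the
published values: they hinge on the proximal-femur lever arms and on the
real patients' neck anatomy, neither of which is published.  Real bones
also differ from the model in ways that do not enter any measured
quantity here (non-circular shaft bow, condylar asymmetry, joint-surface
geometry); conclusions about such features cannot be drawn from these
simulations.  Baseline-plane rotations are *nearly* invariant, not exactly:
the 42°-antetorsion model shows up to ~0.7° of HKA change at 30° rotation
through its anterior neck offset, consistent with the published tendency
of proximal rotational osteotomies to shift alignment slightly.
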