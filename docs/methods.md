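# Methods

## Coordinate and display conventions

All image-frame computations use origin at the top-left pixel, x to the
right, y downward, 0-based indices, and half-open boxes
[x0, x1) × [y0, y1).  Standard radiographic display is assumed — the
patient's right side appears on the viewer's left — so the medial
direction of a right leg is +x.  The assumption is a config flag
(`standard_display`) because the fibula-lateral side rule and the varus
sign both depend on it.

## Angle model

Let **F**, **T** be the distally-oriented mechanical axes of femur and
tibia and **S** the anatomical femoral shaft axis.  The signed
varus(+)/valgus(−) rotation δ(a→b) between two distal directions is
computed from atan2 of their cross and dot products, sign-flipped with the
leg side so that rotation toward the medial side is positive on either
leg.  Then

* mFAmTA = 180° − δ(**F**→**T**)  (neutral 180°, varus < 180°),
* FSAmTA = 180° − δ(**S**→**T**),
* mMPTA = angle(−**T**, medial plateau ray),
* mLDFA = angle(−**F**, lateral condylar ray),
* mLDTA = angle(−**T**, lateral ankle ray).

The 180°-based convention is used because alignment is conventionally
reported as an angle rather than a deviation; subtract from 180° to get
the deviation form.  Joint-line rays are oriented medially/laterally from
the role-tagged landmark pairs themselves (medial edge → lateral edge),
which makes every angle mirror-stable by construction; the suite checks
mirror stability to 1e-9°, and rigid/scale invariance to 1e-6°.

The shaft axis **S** is defined so that δ(**S**→**T**) equals the varus
angle plus the anatomical–mechanical femoral offset, i.e. FSAmTA =
mFAmTA − offset (≈ 174° for a neutral leg with the default 6° offset), the
conventional femorotibial-angle reading.

### Axis construction

* Hip center: algebraic least-squares (Kåsa) circle fit to the
  femoral-head contour landmarks — exact when the points lie on a circle.
* Knee centers: condylar-notch landmark (native) or the midpoint of the
  femoral component's distal tangent pair (TKA); tibial side from the
  tibial-spine midpoint (native) or the tray-edge midpoint (TKA).
* Ankle center: midpoint of the two talar-dome landmarks.  The ankle
  joint line is likewise taken from these two landmarks: the talus region
  carries exactly two landmarks, so a separate plafond line is not
  constructible, and the talar-dome reading is used consistently.
* Shaft axis: least-squares line through per-row centroids of the femur
  mask over rows at 40–70% of the femur's vertical extent (clear of head,
  neck and condyles).  Masks are polygonal where available — predicted
  masks are polygons — and the row "centroid" is then the exact midpoint
  of the horizontal chord, which makes the fit analytic on the oracle
  path; on rasterized masks the pixel-row centroid is used instead (the
  suite requires 0.1° on a 7°-rotated raster rectangle).

### Availability as data

Every parameter lists its prerequisites (structures, landmark roles, the
side rule).  A failure anywhere — structure not detected, landmark below
the peak threshold, indeterminate side — marks only the dependent
parameters unavailable, each carrying a machine-readable reason; a
missing talus therefore leaves exactly {mLDFA}, while a failed
proximal-femur landmark stage leaves {mMPTA, mLDTA, FSAmTA} (the shaft
axis comes from the mask, not from landmarks).  Detection rates are the
per-parameter fraction of legs with an available value.

## Phantom generator

The phantom is a geometric stick-figure leg: femoral head disc, neck and
shaft capsules, condylar and plateau trapezoids, a thin fibular capsule
lateral to the tibia, a talar dome, and optionally a two-component knee
implant (femoral band + tibial tray-and-stem).  Intensities before
blur/noise are 0.1 background, 0.6 bone, 0.95 implant (implants are the
brightest structures on radiographs); rendering applies a Gaussian blur
(default σ 1.2 px) and additive Gaussian noise (default SD 0.02), clipped
to [0, 1].  One integer seed determines everything.

The construction is driven directly by the generating angles — the
varus/valgus angle rotates the tibial axis, each joint-line obliquity
tilts its line about the corresponding center, the anatomical–mechanical
offset tilts the shaft — so the five parameters have closed forms
(mFAmTA = 180 − varus, mMPTA = 90 − plateau obliquity, and so on) and the
landmark/mask ground truth is exact.  Landmark schemas are the same
objects the landmark models consume.  Default morphometry (bone lengths
~270–300 px, joint half-widths 36–46 px at a 768×384 frame) was chosen
once for plausible proportions; sampled ranges default to ±8° varus,
5–7° anatomical offset and ±4° obliquities, spanning normal to clearly
pathological alignment.

What the phantom does *not* emulate: soft tissue, osteophytes and
osteoarthritic deformity, hip implants, stitching artifacts, exposure
variation.  Passing phantom-based tests therefore demonstrates the
correctness of the geometry, transforms, accounting and statistics and
the *trainability* of the learned stages — not clinical-grade accuracy on
real radiographs.

## Trainable stages

Both learned operators are small encoder–decoder per-pixel convolutional
networks written on an in-package numpy toolkit (im2col convolutions,
ReLU, average pooling, nearest upsampling, Adam), fully seeded and
serialized as single-file `.npz` checkpoints.  Inputs carry normalized
coordinate channels and Gaussian-smoothed copies of the intensity
alongside the image, which lets very small nets resolve position-dependent
structure.

**Segmenter** — 6 conv layers at 128×128 input, softmax over
7 classes (background + 6 structures) with inverse-√frequency class
weights (the talus covers ~1% of pixels and would otherwise be learned
last); default learning rate 0.002.
Exactly ⌊n/2⌋ of the training images are flip-augmented, making the model
side-insensitive.  Instances are connected components of the upsampled
class map, scored by mean class probability; score threshold 0.5, NMS by
mask-IoU 0.5, at most two instances per label (bilateral images).

**Landmark models** — one per region, 11 conv layers over a 3-level
encoder at 128×128 internal resolution, one output channel per landmark.
Training targets are Gaussian heatmaps (σ = 5 px at the 256 crop) and the
loss is per-channel *spatial softmax cross-entropy*: each channel is
softmax-normalized over its pixels and scored against the mass-normalized
target.  Plain MSE was found to tolerate bimodal channels that confuse
mirror-sibling landmarks; the spatial cross-entropy penalizes stray modes
directly.  Augmentation rotates ±10° and scales 0.9–1.1 with landmark
coordinates co-transformed; default learning rate 0.001, batch size 1.
At inference each channel's softmax map is rescaled so its peak equals
the channel's mass concentration (probability mass in the 3×3 window at
the argmax), making peak heights comparable across channels of very
different sharpness.  Decoding takes each channel's argmax refined by a
3×3 center of mass; confidence is the channel peak over the global
maximum, and peaks under `peak_threshold` (default 0.2) mark the
landmark missing.

A known residual: the five femoral-head contour points are rotationally
ambiguous (any point on a circle looks like any other), so their
*identities* are sometimes permuted even when every predicted point lies
on the head contour.  This leaves the circle-fitted hip center — the only
quantity the geometry consumes — essentially unaffected, which is why the
proximal-femur per-landmark error can be large while end-to-end angle
accuracy stays well under a degree.

### Scaled-down study sizes

The validation suite trains the segmenter on 30 phantoms for 20 epochs
and each landmark model on 40 crops for 30 epochs, evaluating on held-out
phantoms (10 for IoU and landmark error, 30 end-to-end).  These sizes are
the package's chosen smoke-test conditions: large enough that held-out
bone IoU ≥ 0.6, talus/knee landmark error ≤ 3 px and end-to-end angle
RMSE ≤ 2° (the upper edge of typical human-vs-automatic disagreement)
are meaningful, small enough to run routinely on one CPU.

## Reliability statistics

Differences d = a − b per parameter over pairwise-complete subjects:
mean with exact t-interval, SD with n−1 denominator,
RMSE = √(mean d²) (so RMSE² = ME² + SD²·(n−1)/n identically), Pearson r
with the two-sided t-test p-value, and ICC(A,1) — two-way model, absolute
agreement, single measure — from ANOVA mean squares, with the
F-distribution confidence interval of McGraw & Wong.  The two-way
absolute-agreement single-measure form is the standard reading for a
fixed pair of raters scored for interchangeability; the implementation is
cross-checked in the tests against an explicit sums-of-squares oracle, an
independent library implementation, and the closed-form variance-ratio
target ICC = 9/10 under the simulated two-rater design (between-subject
SD 3°, rater noise SD 1°).

## Numerical notes and edge cases

* Crop transforms compose offset, optional flip (at the 256-wide crop
  frame) and per-axis corner-convention scales; round-trips are exact to
  1e-9 px, so landmark back-projection inherits no resampling error.
* Histogram equalization is the contrast enhancement (deterministic,
  parameter-free); constant crops short-circuit to a constant image.
* Circle fit with < 3 or collinear points, shaft fits with < 50 usable
  rows, ICC with zero total variance, Pearson with constant input, and
  agreement with < 2 pairs all raise typed errors; batch measurement
  converts per-image failures into all-unavailable reports instead of
  aborting.
* Angles are reported at full precision in JSON and rounded to 0.1° in
  human-facing output.

## Limitations

The renderer is deliberately non-photorealistic; trained-stage results on
phantoms bound what the architecture can learn, not clinical performance.
Unicondylar implants, plates, hip implants, multi-frame DICOM and image
stitching are out of scope.  The joint-line convergence angle, leg-length
measurement and joint-line orientation relative to the floor are natural
extensions the axis bundle already supports but are not implemented.
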