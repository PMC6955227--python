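# Methods

This note records the models, conventions, parameter choices and known
limitations behind `frogswim`, in the spirit of a methods appendix.

## Coordinate and angle conventions

Frames are `(H, W, 3)` uint8 RGB arrays indexed `frame[y, x]`; `x` grows
rightward, `y` downward. The *oriented body frame* of a head-up,
dorsally viewed animal has `+x` toward the animal's right and `+y`
toward the posterior (with the head pointing up in a dorsal view, the
animal's right coincides with the image's right). A body heading of
φ degrees tilts the body-axis line to 90 + φ versus the horizontal.

Hindfoot angles are measured at the center of gravity between the
lateral ray of that side and the vector to the foot, sweeping toward the
posterior, in [0°, 180°): 0° = foot straight lateral, 90° = straight
posterior. The convention is mirrored between sides, so a
mirror-symmetric posture gives α_R = α_L. Angle values that land
slightly anterior of the lateral ray (detection noise) are clamped to
the nearer end of the range. The center of gravity used as the angle
vertex is the centroid of the *limb-free* (morphologically opened) body:
the full-silhouette centroid is displaced a few pixels toward the
posterior because the hindlimbs outweigh the forelimbs, and the body
centroid is the stable anatomical reference. The alternative reading —
measuring each angle at the hip joint — would give systematically larger
sweeps; the vertex is a single convention applied consistently to the
angle-pair, the histogram and the range feature.

## Synthetic videos and the stroke model

The renderer draws a filled body ellipse (axial semi-axis 40 px, lateral
22 px at the default 512×384 frame) and four rigid limb segments of
constant length (48 px hind, 26 px fore) attached at fixed
posterolateral/anterolateral anchor points on the body outline. The
limb endpoint sits where the circle of the limb's length around its
anchor meets the ray from the body center at the ground-truth angle —
keeping the drawn limb area constant across the stroke, which in turn
keeps the whole silhouette's area within about ±2.5 % across frames
(comfortably inside the tracker's ±10 % acceptance band). The animal
drifts at 0.8 px/frame along a heading that wobbles sinusoidally by ±3°
at the stroke frequency. Foreground/background colors are chosen so the
blue channel separates them strongly (40 vs 230).

Hindfoot angle traces follow
`α(t) = mean + amplitude · sin(2π f t [+ offset + jitter]) + noise`,
clipped to [0°, 180°), with the phase offset and a *per-stroke* phase
jitter (one Gaussian draw per stroke cycle) on the left trace. The
class-typical parameters are:

| class | amp R | amp L | mean R | mean L | offset | noise SD | jitter SD |
|---|---|---|---|---|---|---|---|
| uninjured  | 43°  | 43° | 56° | 56° | 0 | 3° | 0.08 |
| hemisected | 21.5°| 43° | 35° | 56° | 0 | 3° | 2.5 |
| transected | 14°  | 14° | 50° | 50° | π | 1.5° | 0.08 |

with per-animal variation (a common amplitude scale in [0.92, 1.08], a
mean shift in ±4°, stroke frequency in [1.7, 2.3] Hz) drawn
deterministically from the animal's seed. These constants were set so
the *derived features* land in the regions that distinguish the classes:
in-phase equal strokes whose measured range of motion comes out near
97° for uninjured animals; a right stroke of half the left's extent with
per-stroke phase resampling (correlation ≈ 0, through-origin slope
≈ 0.5) for hemisected ones; and small anti-phase wiggles (correlation
≈ −1, range near 38°) for transected ones, whose pelvis rocking reads as
inverted foot motion. Note the amplitudes are smaller than half the
target ranges because the KDE smoothing in the range feature widens the
measured arc by roughly 10° (see below). Forelimbs oscillate mildly
(amplitude 12° about 42°) and identically across classes — they are
tracked but carry no class signal, as forelimb function is spared by
these lesions.

What the generator does *not* emulate: water refraction and shadows,
body flexion and limb articulation (knee/ankle joints), perspective and
lens distortion, lighting gradients, occlusions at the container wall,
and turning maneuvers. Tests passing on synthetic videos therefore
demonstrate the correctness of the image-processing chain and the
feature definitions under the stated geometry — not robustness to the
full variability of laboratory footage.

## Segmentation and tracking

Thresholding uses Otsu on the blue channel by default (a fixed value is
configurable); the animal is assumed darker than the background, and a
mask whose foreground covers most of the frame raises a polarity error
unless explicitly overridden. Area calibration measures the largest
thresholded component in six uniformly sampled frames (seeded) and takes
the median; the acceptance band is the paper-standard ±10 %. The
tracking window is a square whose side defaults to 3× the diameter of
the disc with the calibrated area — wide enough to contain fully
extended limbs at the default geometry (a 2× factor clips them). Ties
in the nearest-to-previous rule break toward the lower component label;
the first processed frame takes the largest in-range component. A frame
with no surviving component yields an invalid detection that carries the
window forward, so tracking re-acquires when the animal reappears.

## Pose estimation

The body used for orientation is the mask eroded with a disc of radius
0.25·√(area/π) (≈ 9 px at defaults) — wider than a limb, narrower than
the body's semi-minor axis. Orientation comes from the region's
principal axis; a region with axis ratio < 1.2 is rejected as degenerate
(a circle has no heading). Head-up normalization rotates the body axis
vertical using bilinear interpolation of the mask indicator thresholded
at 0.5 (markedly smoother limb outlines than nearest-neighbor), then
flips 180° iff the top half holds strictly more foreground pixels than
the bottom — the posterior half (hindlimbs + pelvis) is the heavier one;
ties do not flip.

Limb extraction subtracts the *opened* body (erosion followed by
dilation with the same disc) rather than the raw eroded mask: plain
subtraction would leave a ring of body boundary in the "limb" image,
while opening restores the body outline and leaves exactly the thin
appendages. Joint zones are dilation(limbs) ∩ dilation(body) with a
2 px disc. Skeleton endpoints (skeleton pixels with exactly one
8-connected neighbor) are candidate feet, except those lying inside a
joint zone — those are where a limb was cut off at the body, not
anatomy.

Assignment of endpoints to the four limbs follows the
furthest-from-joint rule per body quadrant, implemented per *limb
component* with anatomically anchored references: each limb's joint
reference is the body-outline point in its quadrant's attachment
direction (70° below lateral for hips, 65° above for shoulders,
estimated from the body ellipse), and its candidate endpoints are those
of the limb component attached there. This matters because a hindfoot
sweeping past 90° crosses the body midline, and two synchronized crossed
limbs merge into a single component: partitioning endpoint *positions*
by quadrant then mislabels the feet, whereas a crossed foot is further
from its own hip than the other foot, so furthest-from-joint inside the
merged component recovers the correct identity. When both limbs of a
girdle still elect the same endpoint, the pair is re-matched by a
bilateral-symmetry prior (the assignment making the two hip-to-foot
distances most similar, since the limbs have equal length); if only one
candidate exists (feet fused into one blob at the stroke extreme), the
nearer limb keeps it and the other limb is invalid for that frame.
Frames with an invalid hindfoot yield an invalid angle-pair and are
skipped by the features — at the default uninjured kinematics this
discards roughly 5 % of frames, concentrated at stroke extremes.

On 200-frame default synthetic videos of each class, recovered angle
traces agree with the ground truth to < 1° mean absolute error with
|bias| < 0.5°; occasional crossed-feet frames deviate by several
degrees, which the density threshold of the range feature absorbs.

## Features

Synchronization is the Pearson correlation of the valid (α_R, α_L)
series (Spearman selectable); it is undefined, and reported as missing,
for fewer than two valid pairs or a motionless (zero-variance) trace —
on real animals the pelvis always induces some foot motion, so this
arises only on degenerate synthetic input. Symmetry is the
least-squares slope of α_R on α_L constrained through the origin,
β = Σ(α_R·α_L)/Σ(α_L²); an intercept-including first-order fit is
available by flag, reporting its slope.

The range features smooth the per-frame hindfoot positions (in the
oriented body frame, relative to the center of gravity) with a binned
Gaussian KDE on a 1 px grid, convolve with an extra Gaussian of σ = 1
cell, threshold at 5 % of the density maximum, and return the arc
between the minimum- and maximum-angle surviving grid points. The
default KDE bandwidth is a fixed 3 px — the scale of per-frame foot
detection noise. Silverman's rule (available as `kde_bandwidth: null`)
assumes roughly Gaussian scatter; foot positions concentrate on a thin
arc, for which it prescribes a ~12 px bandwidth and widens the measured
range by some 20°. Even at 3 px the smoothing-plus-threshold halo adds
about 10° beyond twice the stroke amplitude, which the synthetic stroke
amplitudes account for. Histogram bins are 1°×1°, value 180 clamps into
bin 179, and the heatmap is min–max normalized with an all-equal
histogram mapping to zeros.

## Classification

Ten classifiers are wrapped behind one factory; features are z-scored
with statistics fitted on the training folds only (toggleable), so
degree-valued ranges and unit-interval correlations are commensurable
for the distance-based methods. The Mahalanobis classifier uses
per-class means and ridge-regularized covariances; QDA carries a mild
covariance regularization (reg_param 10⁻³) because a clean synthetic
class can have nearly collinear features (right and left range of a
transected animal), which makes the unregularized estimate singular —
an issue real cohorts rarely exhibit. The shallow network is a single
hidden layer of 10 units with seed-fixed initialization. KNN ties
follow scikit-learn's ordering convention. Cross-validation is
stratified 10-fold (≈ 3 animals per class per test fold at the standard
90-animal cohort), repeated 10 times with seed-deterministic shuffles;
accuracy is reported as the mean ± standard deviation over all fold
accuracies. Chance-level checks against permuted labels use the
binomial standard error of an accuracy estimated from the 90 held-out
predictions of one repeat — repeats reuse the same animals and add no
independent information; note also that cross-validation on permuted
labels is mildly pessimistic (below-chance) by construction, which stays
well within three such standard errors.

## Numerical and degenerate-input policy

Uniform frames threshold to an empty mask; videos with zero valid
detections raise an explicit error rather than emitting empty features.
Pose estimation raises a typed `PoseError` for empty, limbless or
orientation-degenerate masks, and the pipeline logs and skips such
frames. All randomness flows through `numpy.random.default_rng` seeded
from user-visible integers; identical seeds give bit-identical
ground-truth tables, detections and cross-validation folds.

## Problem sizes used in the shipped checks

The test suite renders 200-frame videos per class at 512×384 for
ground-truth recovery, 40-frame clips for geometry properties, and a
90-animal trace-level cohort (600 frames each, no rendering) for the
classification harness; the benchmark script samples a few hundred
trace points per quantity. These sizes give stable statistics for every
check while keeping a full run in a few minutes on one CPU.

## Known limitations

Per-frame limb identity is geometric; there is no temporal smoothing, so
a frame where the hindfeet overlap is dropped rather than disambiguated
from context. Angles live in [0°, 180°) — a foot swung anterior of the
lateral ray saturates at 0°. Only single-animal scenes on clean, light
backgrounds are supported, and the learned region-of-interest detector
that would localize the animal in cluttered scenes is a plug-in seam
(`RoiDetector`), not part of the package. Forelimb-based features and
3-D (z-axis) behavior are out of scope.
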