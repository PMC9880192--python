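# Methods

This note records how `podpheno` measures, models and validates — the
assumptions behind each stage, the defaults and why they were chosen, and
what the synthetic experiments do and do not demonstrate.

## Imaging model and preprocessing

The measurement chain assumes a single detached pod on a uniform light
background, photographed orthogonally with a dark square calibration
marker of known physical side (2 cm by default) in the same frame.
Geometric (lens) distortion is assumed corrected upstream; the CLI accepts
pre-rectified images and a manual `--px-per-cm` for marker-less rigs.

Stages, with defaults (all exposed as function/CLI parameters):

1. **Gaussian smoothing**, σ = 1.0 px — enough to suppress sensor noise
   without displacing a 170-gray-level edge.
2. **Canny edges**, thresholds (50, 150) on the 8-bit gradient scale —
   the silhouette edge of a dark pod on a light background produces
   gradient magnitudes well above the high threshold, so hysteresis yields
   one closed chain per object.
3. **Morphological close**, disk radius 2 — seals cracks and concave
   notches narrower than ~4 px in the segmented silhouette. Note that
   closing cannot reconnect a truly broken 1-px edge chain (the eroded
   bridge always loses its unsupported corners); edge continuity comes
   from Canny hysteresis, closing is boundary repair.
4. **Component selection** — interior holes are filled, components below
   200 px discarded, and the marker excluded as the component whose
   bounding-box aspect is nearest 1 with the highest extent (pods are
   elongated; the marker is square and solid). Exactly one component must
   remain.
5. **Sub-pixel boundary refinement** (default on) — the binary boundary of
   the filled edge component rides the outer side of the 1-px Canny ring,
   a bias of about half a pixel that digitization makes anisotropic
   (trait drift up to ~3% under image rotation). The final contour is
   therefore re-traced as the level set of the smoothed image at half the
   local inside/outside contrast around the detected component, which
   recenters the boundary on the true edge. With refinement, all five
   traits change by < 0.7% under arbitrary rotations of the test images.

**Scale calibration.** `px_per_cm` is the marker's mean side length over
its physical side. The side is estimated as the square root of the area of
the marker's sub-pixel boundary polygon — exact for a square and stable
under rotation, whereas the min-area-rectangle side is inflated ~1% by
staircase corners on rotated markers. The rectangle is still computed to
verify squareness (side ratio within [0.8, 1.25]). The marker's pixel
count anchors area calibration independently of the side estimate.

## The five traits

Coordinates are image-frame: origin top-left, x = column, y = row;
contours are stored with positive shoelace area.

* **Length**: the minimum-area rotated rectangle of the contour; length is
  the distance between the midpoints of its two short sides (equal to the
  long side). Reported in cm via `px_per_cm`.
* **Width**: maximum inscribed circle diameter. The default
  (`width_method="centroid_min"`) centers the circle at the polygon
  centroid computed from shoelace moments and takes the radius as the
  minimum centroid-to-boundary distance — the natural reading of an
  inscribed-circle radius anchored at the centroid, since any larger
  radius would cross the boundary. An exact maximal inscribed circle from
  the Euclidean distance transform of the filled interior is available as
  `width_method="distance_transform"`; on straight capsules the two agree
  within 2%, and the chain falls back to the distance transform (with a
  warning) when the centroid falls outside a strongly bent contour. The
  centroid rule under-estimates width on bent pods (the centroid drifts
  toward the concave side); the distance-transform method does not.
* **Area**: template calibration — filled-contour pixel count times the
  marker's physical area over the marker's pixel count. Using pixel counts
  on both sides of the ratio cancels the digitization bias to first
  order.
* **Chord and arc**: computed on the convex hull of the contour ("the
  external polygon"). Hull traversal starts at the vertex nearest the
  mid-height of the leftmost extent. At each hull vertex the turning angle
  between the incoming and outgoing edge vectors is computed from their
  normalized dot product; these angles are accumulated over a sliding
  arc-length window of one sixth of the hull perimeter, and the two
  windowed-curvature peaks at least a quarter perimeter apart are the pod
  tips. Each coarse peak is then recentred (three iterations) on the
  curvature centroid of its window, so a tip whose curvature is
  asymmetric — a sharp corner adjoining a smooth arc — converges onto the
  corner, while the symmetric cap of a capsule keeps its apex. The chord
  is the tip-to-tip Euclidean distance; the arc is the hull perimeter
  minus the chord. A naive "two largest angle differences" rule was
  rejected: on a rasterized capsule hull it selects the side-to-cap
  transition vertices rather than the tips, shortening the chord by up to
  one pod width.

The windowed rule assumes the pod has exactly two high-curvature tips
separated by smoother flanks — true for capsule- and crescent-shaped pods,
not for near-circular objects (rejected anyway by the hull-size guard).

## Synthetic ground truth

A pod is generated as a **stadium** — a centerline segment of length
`L − W` dilated by `W/2` — optionally bent along a circular arc subtending
a given angle, so every trait has a closed form: length `L`, width `W`,
area `(L−W)·W + π(W/2)²`, chord `2(ρ sin(θ/2) + (W/2) cos(θ/2))` for arc
radius `ρ = (L−W)/θ`, and arc defined operationally as hull perimeter
minus chord (for a straight capsule, `L + (π−2)W`). Defaults follow the
mean mature pod of the Heihe 49 variety (4.56 × 1.02 cm) at 50 px/cm;
rendering uses three fixed gray levels (background 230, pod 60, marker 10)
with anti-aliasing off so pixel counts are exact, and the marker is an
axis-aligned square of exactly `round(2 cm × px_per_cm)` px per side.
Rotation augmentation defaults to nearest-neighbour resampling for the
same reason (bilinear available via `order`).

Trait/weight tables draw the five traits uniformly from the observed
mature-pod ranges (length 4.5–5.5 cm, width 0.95–1.2 cm, area 2.5–5 cm²,
chord 3.5–4.5 cm, arc 3.8–5.3 cm) and set
`weight = coeffs · traits + intercept + N(0, σ)` with default coefficients
(0.02, 0.05, 0.12, 0.01, 0.01) g/unit — area-dominated, giving mean
weights near 0.72 g as observed for mature pods — and σ = 0.02 g.

Detection scenes place well-separated ground-truth boxes (pairwise
IOU ≤ 0.1), one jittered high-confidence prediction per ground truth
(IOU kept above 0.5), plus duplicates and spurious boxes at lower
confidence, so the matching outcome (TP = n_gt, FP = n_dup + n_spurious)
is known by construction.

**What passing these suites shows — and does not.** Recovery of traits
within 3% on synthetic capsules demonstrates the geometric estimators and
the calibration logic, under ideal contrast, a clean background, exact
marker geometry and no occlusion. Real pod images add texture, shadows,
specularity, tapering and twisted tips, and contact with other plant
material; none of that is emulated, so field accuracy must be validated
on real data.

## Detection matching and AP

Predictions with confidence ≤ 0.3 are discarded (strict inequality, as is
the IOU > 0.5 test); the rest are processed in strictly descending
confidence, ties broken by input order, each claiming its maximum-IOU
ground truth; a hit on an already-matched ground truth is a false
positive ("matched for the first time"). FN counts unmatched ground
truths — needed for recall even where only TP/FP are tabulated. The PR
curve re-runs the matching at every distinct confidence value; AP
integrates the monotone precision envelope (all-point interpolation), with
a raw trapezoid option (`ap_method="trapezoid"`). With a single class,
mAP = AP. Boxes are continuous-coordinate with area `(x2−x1)(y2−y1)`; no
+1-pixel convention.

## EIOU and coordinate attention conventions

In the EIOU loss, `c_w`/`c_h`/`c²` come from the smallest rectangle
enclosing *both* boxes, making all three penalty terms dimensionless and
bounded; `ρ²(w, w^gt)` is the squared scalar width difference. In the
coordinate-attention block the channel-reducing transform uses ReLU and
the gates use the logistic sigmoid; the output multiplies the input by
both the per-row gate `g^h` and the per-column gate `g^w` (the standard
two-factor form — a one-factor variant would leave `g^h` computed but
unused). These are forward-only reference implementations; gradients are
only probed by finite differences in the tests.

## The 5-120-1 weight network

Fully connected, 5 trait inputs → 120 logistic-sigmoid hidden units → 1
linear output, trained by full-batch gradient descent on the mean squared
error, weights initialized uniform(−0.5, 0.5) from the config seed.
Inputs and target are min-max normalized to [0, 1] before training —
sigmoid hidden units saturate on raw cm/gram scales. Training stops at a
target MSE of 0.01 on the normalized targets (the reported training
protocol) or at the epoch budget.

The learning rate is cost-guarded ("bold driver"): it starts at 0.01,
grows 5% after every epoch whose cost improved, up to a ceiling of 0.8,
and halves on any cost increase. A fixed-rate mode exists. The ceiling is
the reported optimum, but plain full-batch descent on a 120-unit sigmoid
layer has a curvature-stability bound near lr ≈ 0.03 (the output-layer
Hessian's top eigenvalue is ≈ 2·Σ E[h_j²] ≈ 60), so an unguarded 0.8 — or
even 0.1 — oscillates; the guard realizes "gradually increased according
to training cost" while settling just under the stable bound. Loss
monotonicity is guaranteed (and tested) only in the clearly stable
fixed-rate regime (0.01). Divergence to non-finite loss raises, naming the
epoch. A constant-target table is fitted exactly without descent
(degenerate normalization).

For parameter-recovery experiments on synthetic data the stop criterion is
set at the generator's known noise floor on the normalized scale,
`max((σ/0.4)², 10⁻⁴)` for weight span ≈ 0.4 g — the 0.01 default would
under-fit low-noise data (stopping at 0.01 on min-max-normalized
uniform targets caps attainable R² near 0.88). At σ = 0.02 g, n = 100,
80/20 split, held-out R² is ≈ 0.92 on average but fluctuates ±0.05 across
seeds purely from the 20-sample test set; recovery checks therefore
average R² over five fixed replicates.

Per-plant weight is `single-pod weight × pods per plant`, reported to
3 decimals; totals take an explicit plant-count/scale factor (it is not
inferred), and relative errors are `|pred − measured| / measured`.

## Problem sizes and numerical choices

The shipped experiments use 20 pods per recovery cohort at 50 px/cm
(420 × 560 px frames), 3 detection scenes of 12 ground-truth boxes, and
n = 100–200 trait/weight rows — sizes at which every suite completes in
seconds on one CPU while keeping relative digitization error below 1%.
Traits are reported to 2 decimals, weights and relative errors to 3,
matching the field's reporting precision. Ties in hull traversal and
prediction ordering are broken by traversal/input order; degenerate
inputs (empty masks, multiple pods, zero-area boxes, zero measured
weights) raise with the failing stage named rather than returning
defaults.

## Known limitations

* Single pod per frame; no segmentation of touching or occluded pods, no
  on-plant (in-situ) measurement, no color-based segmentation.
* The centroid width rule biases low on strongly curved pods; prefer
  `distance_transform` there.
* The BP network is a fixed 5-120-1 topology; no architecture search,
  regularization or uncertainty quantification.
* Detector training itself (the full network, its attention placement and
  loss wiring) is out of scope: the package provides the loss/attention
  reference functions and the evaluation protocol, not a trainable model.
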