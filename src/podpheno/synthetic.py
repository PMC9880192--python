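"""Synthetic pod images, detection scenes and trait/weight tables.

Every measurement routine in this package is validated against data whose
ground truth is known analytically, generated here:

* **Pod silhouettes** — a pod is rendered as a *stadium* (a rectangle with
  semicircular caps), optionally bent along a circular arc, on a light
  background together with a dark square calibration marker of known
  physical side (2 cm by default).  Because the generating curve is
  analytic, all five phenotypic traits (length, width, area, chord, convex
  arc) are known exactly before rasterization.
* **Detection scenes** — ground-truth boxes plus jittered, duplicate and
  spurious predictions with confidences, so TP/FP matching outcomes are
  known by construction.
* **Trait→weight tables** — five traits drawn uniformly from per-trait
  ranges and a weight that is a linear map of the traits plus Gaussian
  noise, emulating the trait distributions of mature pods (length about
  4.5–5.5 cm, width about 0.95–1.2 cm).

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .boxes import Box
from .phenotype import PodPhenotype
from .yield_model import TRAIT_COLUMNS

__all__ = [
    "PodShapeSpec",
    "DetectionSceneSpec",
    "YieldDatasetSpec",
    "BACKGROUND_GRAY",
    "POD_GRAY",
    "MARKER_GRAY",
    "analytic_phenotype",
    "generate_pod_image",
    "generate_detection_scene",
    "generate_yield_dataset",
    "augment",
]

# Fixed rendering grays: the study images have dark pods and a darker
# marker on a light background; exact values are free choices made once so
# that edge detection and marker thresholds are deterministic.
BACKGROUND_GRAY = 230
POD_GRAY = 60
MARKER_GRAY = 10

# Table-4-style mean traits of a mature pod (cm / cm2): length, width,
# area, chord, arc.
DEFAULT_TRAIT_MEANS = (4.56, 1.02, 4.11, 3.85, 4.34)

# Trait ranges of mature pods (cm / cm2): length 4.5-5.5, width 0.95-1.2,
# area 2.5-5, chord 3.5-4.5, arc 3.8-5.3 — the observed spread at maturity.
DEFAULT_TRAIT_RANGES = (
    (4.5, 5.5),
    (0.95, 1.2),
    (2.5, 5.0),
    (3.5, 4.5),
    (3.8, 5.3),
)


@dataclass(frozen=True)
class PodShapeSpec:
    """Geometry of one synthetic pod plus the marker and raster layout.

    ``bend_angle_deg`` is the total angle subtended by the circular arc the
    pod's centerline follows; 0 is a straight capsule.  ``length_cm`` is
    the curvilinear tip-to-tip length, ``width_cm`` the tube width.
    """

    length_cm: float = 4.56
    width_cm: float = 1.02
    bend_angle_deg: float = 0.0
    px_per_cm: float = 50.0
    image_size: tuple[int, int] = (420, 560)
    marker_cm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_cm <= 0 or self.width_cm <= 0 or self.px_per_cm <= 0:
            raise ValueError("length, width and px_per_cm must be positive")
        if self.width_cm >= self.length_cm:
            raise ValueError(
                f"width {self.width_cm} must be smaller than length {self.length_cm}"
            )
        if not 0.0 <= self.bend_angle_deg <= 90.0:
            raise ValueError("bend angle must be in [0, 90] degrees")
        if self.marker_cm <= 0:
            raise ValueError("marker side must be positive")


@dataclass(frozen=True)
class DetectionSceneSpec:
    """One synthetic detection fixture: ground truth plus scored predictions."""

    gt_boxes: tuple[Box, ...]
    predictions: tuple[tuple[Box, float], ...]
    image_size: tuple[int, int]

    def __post_init__(self) -> None:
        rows, cols = self.image_size
        for b in self.gt_boxes + tuple(p for p, _ in self.predictions):
            if b.x1 < 0 or b.y1 < 0 or b.x2 > cols or b.y2 > rows:
                raise ValueError(f"box {b} outside image {self.image_size}")
        for _, c in self.predictions:
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"confidence {c} outside [0, 1]")


@dataclass(frozen=True)
class YieldDatasetSpec:
    """Linear trait→weight data-generating process with additive noise."""

    n: int = 100
    coeffs: tuple[float, ...] = (0.02, 0.05, 0.12, 0.01, 0.01)
    intercept: float = 0.0
    noise_sd: float = 0.02
    trait_ranges: tuple[tuple[float, float], ...] = DEFAULT_TRAIT_RANGES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if len(self.coeffs) != 5 or len(self.trait_ranges) != 5:
            raise ValueError("need 5 coefficients and 5 trait ranges")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for lo, hi in self.trait_ranges:
            if lo >= hi:
                raise ValueError(f"trait range ({lo}, {hi}) has low >= high")


# -- pod geometry ----------------------------------------------------------


def _centerline_cm(spec: PodShapeSpec, n_samples: int = 256) -> np.ndarray:
    """Sample the pod centerline in cm, centered on its midpoint.

    The centerline has length ``length_cm - width_cm`` so that the rendered
    tube (centerline dilated by width/2) spans exactly ``length_cm`` tip to
    tip.  For a bent pod the centerline is a circular arc subtending
    ``bend_angle_deg`` with the convex side toward smaller y.
    """
    s = spec.length_cm - spec.width_cm
    theta = math.radians(spec.bend_angle_deg)
    if theta == 0.0:
        t = np.linspace(-0.5, 0.5, n_samples)
        return np.column_stack([s * t, np.zeros(n_samples)])
    rho = s / theta
    phi = np.linspace(-theta / 2, theta / 2, n_samples)
    # arc center at (0, rho); midpoint of the arc at the origin
    return np.column_stack([rho * np.sin(phi), rho * (1.0 - np.cos(phi))])


def analytic_phenotype(spec: PodShapeSpec) -> PodPhenotype:
    """Closed-form traits of the generating capsule, in cm / cm².

    ``chord`` is the distance between the two tips (centerline endpoints
    pushed out by width/2 along the tangents); ``arc`` is the convex-hull
    perimeter minus the chord, the same operational definition the
    measurement chain uses.
    """
    length, w = spec.length_cm, spec.width_cm
    r = w / 2.0
    s = length - w
    theta = math.radians(spec.bend_angle_deg)
    area = s * w + math.pi * r * r
    if theta == 0.0:
        chord = length
        hull_perimeter = 2.0 * s + math.pi * w
    else:
        rho = s / theta
        half = theta / 2.0
        chord = 2.0 * (rho * math.sin(half) + r * math.cos(half))
        # hull of the bent tube = (hull of the centerline arc) dilated by r:
        # perimeter = arc length + arc chord + 2*pi*r
        hull_perimeter = s + 2.0 * rho * math.sin(half) + 2.0 * math.pi * r
    arc = hull_perimeter - chord
    return PodPhenotype(
        length_cm=length, width_cm=w, area_cm2=area, chord_cm=chord, arc_cm=arc
    )


def _pod_mask(
    spec: PodShapeSpec, center_px: tuple[float, float], shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize the pod: pixels whose center is within width/2 of the centerline."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    # pixel centers in cm, relative to the pod anchor
    px_cm = (xx - center_px[0]) / spec.px_per_cm
    py_cm = (yy - center_px[1]) / spec.px_per_cm
    r = spec.width_cm / 2.0
    s = spec.length_cm - spec.width_cm
    theta = math.radians(spec.bend_angle_deg)
    if theta == 0.0:
        # distance to the horizontal segment [-s/2, s/2] x {0}
        dx = np.abs(px_cm) - s / 2.0
        d = np.hypot(np.maximum(dx, 0.0), py_cm)
    else:
        rho = s / theta
        vx, vy = px_cm, py_cm - rho  # relative to the arc center (0, rho)
        phi = np.arctan2(vx, -vy)
        on_arc = np.abs(phi) <= theta / 2.0
        d_arc = np.abs(np.hypot(vx, vy) - rho)
        half = theta / 2.0
        e1 = (rho * math.sin(half), rho * (1.0 - math.cos(half)))
        d_end = np.minimum(
            np.hypot(px_cm - e1[0], py_cm - e1[1]),
            np.hypot(px_cm + e1[0], py_cm - e1[1]),
        )
        d = np.where(on_arc, d_arc, d_end)
    return d <= r


def _pod_extent_cm(spec: PodShapeSpec) -> tuple[float, float]:
    """(width, height) in cm of the pod's axis-aligned bounding box."""
    r = spec.width_cm / 2.0
    theta = math.radians(spec.bend_angle_deg)
    ph = analytic_phenotype(spec)
    if theta == 0.0:
        return spec.length_cm, spec.width_cm
    s = spec.length_cm - spec.width_cm
    rho = s / theta
    sag = rho * (1.0 - math.cos(theta / 2.0))
    return ph.chord_cm + 2 * r, sag + 2.0 * r  # conservative horizontal extent


def generate_pod_image(
    spec: PodShapeSpec,
) -> tuple[np.ndarray, PodPhenotype, np.ndarray]:
    """Render one pod plus marker; return (image, analytic traits, contour).

    The image is uint8: background 230, pod 60, marker 10; the marker is an
    axis-aligned square of exactly ``round(marker_cm * px_per_cm)`` pixels
    per side, stacked above the pod.  The returned contour is the analytic
    outline of the capsule in pixel coordinates (x, y), counter-clockwise.
    Raises if pod or marker (with margins) do not fit in ``image_size``.
    """
    rows, cols = spec.image_size
    margin = 6
    gap = 20
    marker_px = int(round(spec.marker_cm * spec.px_per_cm))
    pod_w_cm, pod_h_cm = _pod_extent_cm(spec)
    pod_w_px = pod_w_cm * spec.px_per_cm
    pod_h_px = pod_h_cm * spec.px_per_cm

    if pod_w_px + 2 * margin > cols or marker_px + 2 * margin > cols:
        raise ValueError(
            f"content too wide for image cols={cols}: pod {pod_w_px:.0f} px, "
            f"marker {marker_px} px (plus margins)"
        )
    stack_h = marker_px + gap + pod_h_px
    if stack_h + 2 * margin > rows:
        raise ValueError(
            f"content too tall for image rows={rows}: marker {marker_px} px + "
            f"gap {gap} px + pod {pod_h_px:.0f} px (plus margins)"
        )

    img = np.full((rows, cols), BACKGROUND_GRAY, dtype=np.uint8)

    # stack (marker above pod) centered in the frame
    top = (rows - stack_h) / 2.0
    r0 = int(round(top))
    c0 = int(round((cols - marker_px) / 2.0))
    img[r0 : r0 + marker_px, c0 : c0 + marker_px] = MARKER_GRAY

    # pod anchor: the centerline midpoint; for a bent pod the mask extends
    # from the anchor down by sag + r and up by r
    pod_top = top + marker_px + gap
    anchor_y = pod_top + spec.width_cm / 2.0 * spec.px_per_cm
    anchor = (cols / 2.0, anchor_y)
    img[_pod_mask(spec, anchor, (rows, cols))] = POD_GRAY

    truth = analytic_phenotype(spec)
    line = _centerline_cm(spec) * spec.px_per_cm + np.asarray(anchor)
    outline = LineString(line).buffer(
        spec.width_cm / 2.0 * spec.px_per_cm, quad_segs=64
    )
    contour = np.asarray(outline.exterior.coords)[:-1]
    return img, truth, contour


# -- detection scenes ------------------------------------------------------


def _random_box(
    rng: np.random.Generator, image_size: tuple[int, int]
) -> Box:
    rows, cols = image_size
    w = rng.uniform(40, 80)
    h = rng.uniform(40, 80)
    x1 = rng.uniform(0, cols - w)
    y1 = rng.uniform(0, rows - h)
    return Box(x1, y1, x1 + w, y1 + h)


def generate_detection_scene(
    n_gt: int,
    n_dup: int = 0,
    n_spurious: int = 0,
    jitter_px: float = 2.0,
    seed: int = 0,
    image_size: tuple[int, int] = (480, 640),
) -> DetectionSceneSpec:
    """Build a detection fixture with known matching outcome.

    Produces ``n_gt`` well-separated ground-truth boxes, one jittered
    high-confidence prediction per ground truth (IOU kept above 0.5),
    ``n_dup`` lower-confidence duplicates of existing predictions and
    ``n_spurious`` predictions overlapping no ground truth above 0.5 IOU.
    Under the standard matching rule the scene therefore yields
    TP = n_gt and FP = n_dup + n_spurious.  Deterministic in ``seed``.
    """
    from .boxes import iou  # local import to keep module load light

    if min(n_gt, n_dup, n_spurious) < 0:
        raise ValueError("counts must be non-negative")
    if n_dup > 0 and n_gt == 0:
        raise ValueError("duplicates require at least one ground-truth box")
    rng = np.random.default_rng(seed)
    rows, cols = image_size

    gt: list[Box] = []
    for _ in range(n_gt):
        for _attempt in range(2000):
            cand = _random_box(rng, image_size)
            if all(iou(cand, g) <= 0.1 for g in gt):
                gt.append(cand)
                break
        else:
            raise ValueError(
                f"could not place {n_gt} well-separated boxes in {image_size}"
            )

    preds: list[tuple[Box, float]] = []
    for g in gt:
        for _attempt in range(2000):
            j = rng.uniform(-jitter_px, jitter_px, size=4)
            cand = Box(
                min(max(g.x1 + j[0], 0.0), cols - 1),
                min(max(g.y1 + j[1], 0.0), rows - 1),
                max(min(g.x2 + j[2], cols), 1.0),
                max(min(g.y2 + j[3], rows), 1.0),
            )
            if jitter_px == 0.0 or iou(cand, g) > 0.55:
                preds.append((cand, float(rng.uniform(0.62, 0.95))))
                break
        else:
            raise ValueError("jitter too large: cannot keep IOU above 0.5")

    for _ in range(n_dup):
        src, _ = preds[int(rng.integers(0, n_gt))]
        preds.append((src, float(rng.uniform(0.40, 0.60))))

    for _ in range(n_spurious):
        for _attempt in range(5000):
            cand = _random_box(rng, image_size)
            if all(iou(cand, g) <= 0.5 for g in gt):
                preds.append((cand, float(rng.uniform(0.32, 0.58))))
                break
        else:
            raise ValueError("could not place a spurious box clear of ground truth")

    # distinct confidences make the descending-confidence order unambiguous
    confs = sorted(c for _, c in preds)
    if len(confs) != len(set(confs)):  # pragma: no cover - measure zero
        preds = [(b, c + 1e-9 * i) for i, (b, c) in enumerate(preds)]
    return DetectionSceneSpec(
        gt_boxes=tuple(gt), predictions=tuple(preds), image_size=image_size
    )


# -- trait/weight tables ---------------------------------------------------


def generate_yield_dataset(spec: YieldDatasetSpec) -> pd.DataFrame:
    """Sample a trait/weight table: ``weight = coeffs·traits + intercept + noise``."""
    rng = np.random.default_rng(spec.seed)
    lows = np.array([lo for lo, _ in spec.trait_ranges])
    highs = np.array([hi for _, hi in spec.trait_ranges])
    traits = rng.uniform(lows, highs, size=(spec.n, 5))
    weight = traits @ np.asarray(spec.coeffs) + spec.intercept
    if spec.noise_sd > 0:
        weight = weight + rng.normal(0.0, spec.noise_sd, size=spec.n)
    df = pd.DataFrame(traits, columns=TRAIT_COLUMNS)
    df["weight_g"] = weight
    return df


# -- augmentation ----------------------------------------------------------


def augment(
    image: np.ndarray, mode: str, params: dict | None = None, seed: int = 0
) -> np.ndarray:
    """Simple study-style augmentations: rotation, Gaussian noise, brightness.

    ``rotate`` turns about the image center (same output size, background
    fill); it resamples nearest-neighbour by default, consistent with the
    generator's anti-aliasing-off rendering, so gray levels stay exact
    (``order`` in params selects bilinear etc.).  ``gaussian_noise`` adds
    zero-mean noise of the given ``sd``, ``brightness`` adds a constant
    ``delta``.  Output dtype matches input; deterministic in ``seed``.
    """
    from skimage.transform import rotate as _rotate

    params = dict(params or {})
    img = np.asarray(image)
    if img.ndim not in (2, 3):
        raise ValueError("expected a 2-D or 3-D raster")
    if mode == "rotate":
        angle = float(params.get("angle", 0.0))
        cval = float(params.get("cval", BACKGROUND_GRAY))
        order = int(params.get("order", 0))
        if angle % 360.0 == 0.0:
            return img.copy()
        out = _rotate(
            img.astype(float), angle, resize=False, order=order, mode="constant",
            cval=cval, preserve_range=True,
        )
    elif mode == "gaussian_noise":
        sd = float(params.get("sd", 5.0))
        rng = np.random.default_rng(seed)
        out = img.astype(float) + rng.normal(0.0, sd, size=img.shape)
    elif mode == "brightness":
        out = img.astype(float) + float(params.get("delta", 20.0))
    else:
        raise ValueError(f"unknown augmentation mode {mode!r}")
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(img.dtype)
    return out
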