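"""The five pod phenotypic traits from a contour and a scale calibration.

* **Length** — long axis of the minimum-area (rotated) circumscribed
  rectangle of the contour: the Euclidean distance between the midpoints of
  its two short sides, converted to cm.
* **Width** — diameter of the maximum inscribed circle, per the germplasm
  convention that the widest part of the pod is its width.  The default
  rule places the circle center at the shoelace centroid of the contour
  and takes the radius as the minimum centroid-to-boundary distance; an
  exact maximal-inscribed-circle method based on the Euclidean distance
  transform is available as ``width_method="distance_transform"`` and is
  used automatically when the centroid falls outside a strongly bent pod.
* **Area** — template calibration: pod pixel count times the marker's
  physical area over the marker's pixel count.
* **Chord and arc** — the convex hull of the contour is traversed from the
  point nearest the mid-height of its leftmost extent; turning angles
  between adjacent hull edges (the "vector angle" of each vertex) are
  accumulated over an arc-length window, and the two curvature peaks are
  the pod's tip points.  The chord is the tip-to-tip Euclidean distance;
  the convex arc is the hull perimeter minus the chord.  The chord/arc
  ratio indexes pod straightness: the larger the ratio, the straighter the
  pod.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from shapely import minimum_rotated_rectangle
from shapely.geometry import Point, Polygon
from skimage import draw

from .preprocessing import Contour, ScaleCalibration, preprocess

__all__ = [
    "PodPhenotype",
    "InscribedCircle",
    "pod_length",
    "pod_width",
    "pod_area",
    "chord_and_arc",
    "measure",
]


@dataclass(frozen=True)
class PodPhenotype:
    """The five traits of one pod, in cm / cm²."""

    length_cm: float
    width_cm: float
    area_cm2: float
    chord_cm: float
    arc_cm: float

    def __post_init__(self) -> None:
        vals = (self.length_cm, self.width_cm, self.area_cm2, self.chord_cm, self.arc_cm)
        if min(vals) <= 0:
            raise ValueError(f"traits must be positive: {vals}")
        if self.width_cm > self.length_cm:
            raise ValueError(
                f"width {self.width_cm:.3f} exceeds length {self.length_cm:.3f}"
            )
        if self.chord_cm > self.arc_cm:
            raise ValueError(
                f"chord {self.chord_cm:.3f} exceeds arc {self.arc_cm:.3f}"
            )
        if self.chord_cm > 1.05 * self.length_cm:
            raise ValueError(
                f"chord {self.chord_cm:.3f} exceeds length {self.length_cm:.3f} by >5%"
            )

    def rounded(self, decimals: int = 2) -> "PodPhenotype":
        """Traits rounded for reporting (2 decimals, cm / cm²)."""
        return PodPhenotype(
            *(round(v, decimals) for v in (
                self.length_cm, self.width_cm, self.area_cm2,
                self.chord_cm, self.arc_cm,
            ))
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "length_cm": self.length_cm,
            "width_cm": self.width_cm,
            "area_cm2": self.area_cm2,
            "chord_cm": self.chord_cm,
            "arc_cm": self.arc_cm,
        }


@dataclass(frozen=True)
class InscribedCircle:
    """Maximum inscribed circle: center (m, n), radius R and contour area S (px)."""

    center: tuple[float, float]
    radius_px: float
    area_px: float


def _min_area_rect_corners(contour: Contour) -> np.ndarray:
    rect = minimum_rotated_rectangle(contour.as_polygon())
    if rect.geom_type != "Polygon":
        raise ValueError("degenerate contour: min-area rectangle collapsed")
    return np.asarray(rect.exterior.coords)[:4]


def pod_length(contour: Contour, scale: ScaleCalibration) -> float:
    """Pod length: long axis of the min-area circumscribed rectangle, in cm.

    Measured as the distance between the midpoints of the rectangle's two
    short sides (which equals the rectangle's long side).
    """
    corners = _min_area_rect_corners(contour)
    edges = np.diff(np.vstack([corners, corners[:1]]), axis=0)
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    if min(lengths) <= 0:
        raise ValueError("degenerate contour: collinear points")
    # short sides are the pair (i, i+2) with the smaller length
    i = int(np.argmin(lengths[:2]))
    mid_a = 0.5 * (corners[i] + corners[(i + 1) % 4])
    mid_b = 0.5 * (corners[(i + 2) % 4] + corners[(i + 3) % 4])
    return float(np.hypot(*(mid_a - mid_b))) / scale.px_per_cm


def _rasterize(contour: Contour) -> tuple[np.ndarray, tuple[int, int]]:
    pts = contour.points
    offset = np.floor(pts.min(axis=0)).astype(int) - 1
    shape = tuple((np.ceil(pts.max(axis=0)).astype(int) - offset + 2)[::-1])
    rr, cc = draw.polygon(pts[:, 1] - offset[1], pts[:, 0] - offset[0], shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask, tuple(offset)


def _distance_transform_circle(contour: Contour) -> tuple[tuple[float, float], float]:
    mask, offset = _rasterize(contour)
    dist = ndimage.distance_transform_edt(mask)
    r, c = np.unravel_index(int(np.argmax(dist)), dist.shape)
    return (float(c + offset[0]), float(r + offset[1])), float(dist[r, c])


def pod_width(
    contour: Contour,
    scale: ScaleCalibration,
    method: str = "centroid_min",
) -> tuple[float, InscribedCircle]:
    """Pod width: maximum-inscribed-circle diameter ``D = 2R`` in cm.

    ``centroid_min`` (default) centers the circle at the shoelace centroid
    and takes R as the minimum distance from the centroid to the boundary;
    ``distance_transform`` finds the true maximal inscribed circle on the
    rasterized interior.  If the centroid lies outside the contour (a
    strongly bent pod) the distance-transform method is used with a warning.
    """
    if method not in ("centroid_min", "distance_transform"):
        raise ValueError(f"unknown width method {method!r}")
    area_px = abs(contour.signed_area())
    if method == "centroid_min":
        m, n = contour.centroid()
        if not contour.as_polygon().contains(Point(m, n)):
            warnings.warn(
                "centroid outside contour (strongly bent pod); "
                "falling back to distance-transform width",
                stacklevel=2,
            )
            method = "distance_transform"
        else:
            radius = float(
                np.min(np.hypot(contour.points[:, 0] - m, contour.points[:, 1] - n))
            )
            circle = InscribedCircle(center=(m, n), radius_px=radius, area_px=area_px)
            return 2.0 * radius / scale.px_per_cm, circle
    center, radius = _distance_transform_circle(contour)
    circle = InscribedCircle(center=center, radius_px=radius, area_px=area_px)
    return 2.0 * radius / scale.px_per_cm, circle


def pod_area(contour: Contour, scale: ScaleCalibration) -> float:
    """Pod area by regional pixel counting and template calibration, in cm².

    ``S_d = W_d * S_k / W_k`` with ``W_d`` the filled-interior pixel count
    of the contour and ``S_k``/``W_k`` the marker's physical area and pixel
    count from the calibration.
    """
    if scale.marker_px_area == 0:
        raise ValueError("marker pixel count is zero")
    mask, _ = _rasterize(contour)
    w_d = int(mask.sum())
    return w_d * scale.marker_cm2 / scale.marker_px_area


def _hull_vertices(contour: Contour) -> np.ndarray:
    hull = ConvexHull(contour.points)
    return contour.points[hull.vertices]  # counter-clockwise


def chord_and_arc(
    contour: Contour, scale: ScaleCalibration
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Chord and convex arc length of the pod, in cm, plus the tip points.

    The hull is traversed from the vertex nearest the mid-height of its
    leftmost extent.  Turning angles between adjacent hull edges are
    summed over a sliding arc-length window (one sixth of the hull
    perimeter) and the two windowed-curvature peaks, at least a quarter
    perimeter apart, are the pod tips.  chord = tip-to-tip distance;
    arc = hull perimeter - chord.
    """
    verts = _hull_vertices(contour)
    k = len(verts)
    if k < 5:
        raise ValueError(
            f"convex hull has only {k} vertices; contour too coarse for "
            "endpoint detection"
        )
    # start traversal at the vertex nearest the mid-height of the leftmost extent
    left_x = verts[:, 0].min()
    mid_y = 0.5 * (verts[:, 1].min() + verts[:, 1].max())
    start = int(np.argmin((verts[:, 0] - left_x) ** 2 + 0.25 * (verts[:, 1] - mid_y) ** 2))
    verts = np.roll(verts, -start, axis=0)

    edges = np.roll(verts, -1, axis=0) - verts
    seg = np.hypot(edges[:, 0], edges[:, 1])
    perimeter = float(seg.sum())
    # turning angle at vertex i: between edge (i-1 -> i) and edge (i -> i+1)
    prev = np.roll(edges, 1, axis=0)
    cosang = np.sum(prev * edges, axis=1) / (
        np.hypot(prev[:, 0], prev[:, 1]) * seg
    )
    turning = np.arccos(np.clip(cosang, -1.0, 1.0))

    # arc position of each vertex; windowed curvature over window/2 each side
    pos = np.concatenate([[0.0], np.cumsum(seg)[:-1]])
    window = perimeter / 6.0
    gap = np.abs(pos[None, :] - pos[:, None])
    circ = np.minimum(gap, perimeter - gap)
    kappa = np.where(circ <= window / 2.0, turning[None, :], 0.0).sum(axis=1)

    def refine(k: int) -> int:
        """Recenter a coarse curvature peak on the curvature centroid of its
        window (iterated), so a tip flanked by asymmetric curvature — a
        sharp corner next to a smooth arc — converges onto the corner."""
        for _ in range(3):
            offs = pos - pos[k]
            offs = (offs + perimeter / 2.0) % perimeter - perimeter / 2.0
            in_win = np.abs(offs) <= window / 2.0
            weight = turning[in_win].sum()
            if weight <= 0.0:
                break
            shift = float((turning[in_win] * offs[in_win]).sum() / weight)
            target = (pos[k] + shift) % perimeter
            d = np.abs(pos - target)
            k_new = int(np.argmin(np.minimum(d, perimeter - d)))
            if k_new == k:
                break
            k = k_new
        return k

    tip1 = refine(int(np.argmax(kappa)))
    far = circ[tip1] >= perimeter / 4.0
    if not np.any(far):
        raise ValueError("could not find a second curvature peak on the hull")
    cand = np.where(far)[0]
    tip2 = refine(int(cand[np.argmax(kappa[cand])]))

    p1, p2 = verts[tip1], verts[tip2]
    chord_px = float(np.hypot(*(p1 - p2)))
    arc_px = perimeter - chord_px
    return chord_px / scale.px_per_cm, arc_px / scale.px_per_cm, (p1, p2)


def measure(
    image: np.ndarray,
    width_method: str = "centroid_min",
    round_decimals: int | None = None,
    **preprocess_kwargs,
) -> PodPhenotype:
    """Measure all five traits of the single pod in ``image``.

    Runs the full preprocessing chain (marker calibration included) and the
    four trait calculators.  Errors are tagged with the failing stage.
    ``round_decimals`` rounds the reported traits (2 matches the reporting
    precision of trait tables).
    """
    try:
        contour, scale = preprocess(image, **preprocess_kwargs)
    except Exception as e:
        raise RuntimeError(f"preprocessing failed: {e}") from e
    try:
        length = pod_length(contour, scale)
        width, _circle = pod_width(contour, scale, method=width_method)
        area = pod_area(contour, scale)
        chord, arc, _tips = chord_and_arc(contour, scale)
    except Exception as e:
        raise RuntimeError(f"trait calculation failed: {e}") from e
    pheno = PodPhenotype(
        length_cm=length, width_cm=width, area_cm2=area, chord_cm=chord, arc_cm=arc
    )
    return pheno.rounded(round_decimals) if round_decimals is not None else pheno
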