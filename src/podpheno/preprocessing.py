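"""Image preprocessing: from a raw pod photo to one clean contour + scale.

The measurement chain assumes an isolated pod on a light background with a
dark square calibration marker of known physical side in the same frame.
Preprocessing is the classical sequence: Gaussian smoothing, Canny edge
detection, a morphological close to seal small gaps in the edge map, hole
filling, and extraction of the single pod boundary as an ordered polygon.
The marker gives the pixel↔centimeter scale: its mean side length in
pixels divided by its physical side is the calibration ratio
``px_per_cm``, and its pixel count anchors the area calibration
(pod area = pod pixel count × marker area / marker pixel count).

Coordinate convention used throughout the package: origin at the top-left,
``x`` = column, ``y`` = row, 0-based; contours are stored so that their
shoelace area is positive in this frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely import minimum_rotated_rectangle
from shapely.geometry import Polygon
from skimage import feature, measure, morphology

__all__ = [
    "Contour",
    "ScaleCalibration",
    "gaussian_filter",
    "canny_edges",
    "morph_close",
    "extract_contour",
    "detect_marker",
    "preprocess",
]

DEFAULT_SIGMA = 1.0
DEFAULT_CANNY_LOW = 50.0
DEFAULT_CANNY_HIGH = 150.0
DEFAULT_CLOSE_RADIUS = 2
DEFAULT_MIN_AREA = 200  # px; blobs below this are noise, not pods or markers

_SQUARE_ASPECT = (0.8, 1.25)  # long/short side ratio range accepted as "square"


@dataclass(frozen=True)
class Contour:
    """Closed simple polygon of pixel coordinates, one point per row (x, y).

    Closure is implicit (first point is not repeated).  Stored with
    positive shoelace area in the image frame.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("contour needs an (n >= 3, 2) array of points")
        if self.signed_area() < 0:
            pts = pts[::-1]
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def signed_area(self) -> float:
        """Shoelace area of the closed polygon (positive after construction)."""
        x, y = self.points[:, 0], self.points[:, 1]
        xr, yr = np.roll(x, -1), np.roll(y, -1)
        return 0.5 * float(np.sum(x * yr - xr * y))

    def centroid(self) -> tuple[float, float]:
        """Area centroid of the polygon interior (shoelace moments)."""
        x, y = self.points[:, 0], self.points[:, 1]
        xr, yr = np.roll(x, -1), np.roll(y, -1)
        cross = x * yr - xr * y
        a = 0.5 * float(np.sum(cross))
        m = float(np.sum((x + xr) * cross)) / (6.0 * a)
        n = float(np.sum((y + yr) * cross)) / (6.0 * a)
        return m, n

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    def as_polygon(self) -> Polygon:
        return Polygon(self.points)


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel↔centimeter calibration from the square reference marker."""

    px_per_cm: float
    marker_px_area: int
    marker_cm2: float

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0 or self.marker_cm2 <= 0 or self.marker_px_area <= 0:
            raise ValueError("calibration quantities must be positive")
        expected = self.px_per_cm**2 * self.marker_cm2
        if abs(self.marker_px_area - expected) > 0.05 * expected:
            raise ValueError(
                f"inconsistent calibration: marker_px_area {self.marker_px_area} "
                f"vs px_per_cm^2 * marker_cm2 = {expected:.0f} (>5% off)"
            )

    @classmethod
    def from_px_per_cm(cls, px_per_cm: float, marker_cm: float = 2.0) -> "ScaleCalibration":
        """Manual calibration when no marker is present in the frame."""
        return cls(
            px_per_cm=px_per_cm,
            marker_px_area=int(round((px_per_cm * marker_cm) ** 2)),
            marker_cm2=marker_cm**2,
        )


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img @ np.array([0.299, 0.587, 0.114])
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D or RGB raster, got shape {image.shape}")
    return img


def gaussian_filter(image: np.ndarray, sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Linear Gaussian smoothing; returns a float image of the same shape."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return ndimage.gaussian_filter(_to_gray(image), sigma=sigma)


def canny_edges(
    image: np.ndarray,
    low: float = DEFAULT_CANNY_LOW,
    high: float = DEFAULT_CANNY_HIGH,
    sigma: float = 1.0,
) -> np.ndarray:
    """Canny edge map (1-px-wide edges); thresholds on 8-bit gradient scale."""
    if not 0 <= low < high:
        raise ValueError(f"need 0 <= low < high, got ({low}, {high})")
    return feature.canny(
        _to_gray(image), sigma=sigma, low_threshold=low, high_threshold=high
    )


def morph_close(binary: np.ndarray, kernel_radius: int = DEFAULT_CLOSE_RADIUS) -> np.ndarray:
    """Morphological closing with a disk: seals cracks and concave notches
    narrower than twice the radius in the segmented silhouette."""
    if kernel_radius < 1:
        raise ValueError(f"kernel radius must be >= 1, got {kernel_radius}")
    b = np.asarray(binary, dtype=bool)
    return morphology.closing(b, morphology.disk(kernel_radius)).astype(bool)


def _component_stats(labels: np.ndarray) -> list[dict]:
    out = []
    for p in measure.regionprops(labels):
        h = p.bbox[2] - p.bbox[0]
        w = p.bbox[3] - p.bbox[1]
        aspect = max(h, w) / max(min(h, w), 1)
        out.append(
            {
                "label": p.label,
                "area": p.area,
                "aspect": aspect,  # >= 1; 1 is square
                "extent": p.extent,  # area / bbox area
            }
        )
    return out


def _marker_index(stats: list[dict]) -> int | None:
    """Index of the component that looks most like the square marker."""
    candidates = [
        (i, s)
        for i, s in enumerate(stats)
        if s["aspect"] <= _SQUARE_ASPECT[1]
    ]
    if not candidates:
        return None
    # nearest-square aspect first, then highest fill of its bounding box
    i, _ = max(candidates, key=lambda t: t[1]["extent"] - abs(t[1]["aspect"] - 1.0))
    return i


def _select_pod_mask(
    binary: np.ndarray, min_area: int, exclude_marker: bool
) -> np.ndarray:
    """Fill holes, label, drop the marker component, demand one pod."""
    filled = ndimage.binary_fill_holes(np.asarray(binary, dtype=bool))
    labels = measure.label(filled, connectivity=2)
    stats = [s for s in _component_stats(labels) if s["area"] >= min_area]
    if exclude_marker and len(stats) > 1:
        mi = _marker_index(stats)
        if mi is not None:
            stats = stats[:mi] + stats[mi + 1 :]
    if len(stats) != 1:
        raise ValueError(
            f"expected exactly one pod component, found {len(stats)} "
            f"(min_area={min_area})"
        )
    return labels == stats[0]["label"]


def extract_contour(
    binary: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
    exclude_marker: bool = True,
) -> Contour:
    """Outer boundary of the single pod component in a binary mask.

    Interior holes are filled first.  If several components qualify and
    ``exclude_marker`` is set, the most square, best-filling component is
    dropped as the calibration marker; exactly one component must remain.
    """
    mask = _select_pod_mask(binary, min_area, exclude_marker)
    rings = measure.find_contours(mask.astype(float), 0.5)
    boundary = max(rings, key=len)  # outer ring of the single component
    pts = boundary[:, ::-1]  # (row, col) -> (x, y)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    return Contour(points=pts)


def _refine_contour(
    mask: np.ndarray, smoothed: np.ndarray
) -> Contour | None:
    """Sub-pixel contour at the half-contrast isophote around ``mask``.

    The binary chain localizes the pod to one component but its traced
    boundary rides the outer side of the 1-px edge ring, which digitization
    makes slightly anisotropic.  Tracing the smoothed image's level set at
    half the local inside/outside contrast recenters the boundary on the
    true edge with sub-pixel precision.  Returns None when no usable ring
    is found (caller falls back to the pixel-level boundary).
    """
    inner = ndimage.binary_erosion(mask, morphology.disk(3))
    near = ndimage.binary_dilation(mask, morphology.disk(3))
    outer_band = ndimage.binary_dilation(mask, morphology.disk(6)) & ~near
    if not inner.any() or not outer_band.any():
        return None
    inside_mean = float(smoothed[inner].mean())
    outside_mean = float(smoothed[outer_band].mean())
    level = 0.5 * (inside_mean + outside_mean)
    # suppress everything away from this component (marker, other blobs)
    far_value = outside_mean if outside_mean > inside_mean else inside_mean
    work = np.where(ndimage.binary_dilation(mask, morphology.disk(6)), smoothed, far_value)
    rings = [r for r in measure.find_contours(work, level) if len(r) >= 8]
    if not rings:
        return None
    pts = max(rings, key=len)[:, ::-1]
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        return None
    return Contour(points=pts)


def detect_marker(image: np.ndarray, marker_cm: float = 2.0) -> ScaleCalibration:
    """Find the dark square marker and derive the pixel↔cm calibration.

    The image is thresholded for dark blobs; among them the marker is the
    near-square (bounding-box aspect within [0.8, 1.25]) component with the
    highest extent.  Its mean min-area-rectangle side over ``marker_cm``
    gives ``px_per_cm``; its pixel count is the area anchor.
    """
    gray = _to_gray(image)
    dark = gray < 0.5 * (gray.min() + gray.max())
    labels = measure.label(dark, connectivity=2)
    stats = [s for s in _component_stats(labels) if s["area"] >= DEFAULT_MIN_AREA]
    square = [
        s
        for s in stats
        if s["aspect"] <= _SQUARE_ASPECT[1] and s["extent"] >= 0.5
    ]
    if not square:
        raise ValueError(
            "no near-square dark marker found (aspect within [0.8, 1.25]); "
            "pass the scale manually via --px-per-cm"
        )
    best = max(square, key=lambda s: s["extent"] - abs(s["aspect"] - 1.0))
    mask = labels == best["label"]
    # sub-pixel boundary of the marker (0.5-level between pixel centers)
    ring = max(measure.find_contours(mask.astype(float), 0.5), key=len)
    boundary = Polygon(ring[:, ::-1])
    rect = minimum_rotated_rectangle(boundary)
    corners = np.asarray(rect.exterior.coords)[:4]
    sides = np.hypot(*(np.diff(np.vstack([corners, corners[:1]]), axis=0).T))
    ratio = max(sides[0], sides[1]) / min(sides[0], sides[1])
    if not _SQUARE_ASPECT[0] <= ratio <= _SQUARE_ASPECT[1]:
        raise ValueError(
            f"marker candidate has min-area-rectangle side ratio {ratio:.2f} "
            "outside [0.8, 1.25]; pass the scale manually via --px-per-cm"
        )
    # mean side estimated from the boundary-polygon area: exact for a square
    # and robust to the staircase corners digitization puts on the min-area
    # rectangle of a rotated marker
    mean_side = float(np.sqrt(boundary.area))
    return ScaleCalibration(
        px_per_cm=mean_side / marker_cm,
        marker_px_area=int(mask.sum()),
        marker_cm2=marker_cm**2,
    )


def preprocess(
    image: np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    canny_low: float = DEFAULT_CANNY_LOW,
    canny_high: float = DEFAULT_CANNY_HIGH,
    close_radius: int = DEFAULT_CLOSE_RADIUS,
    marker_cm: float = 2.0,
    px_per_cm: float | None = None,
    min_area: int = DEFAULT_MIN_AREA,
    refine: bool = True,
) -> tuple[Contour, ScaleCalibration]:
    """Full chain: smooth, edge-detect, close, fill, extract contour + scale.

    With ``refine`` (default) the final boundary is re-traced at the
    sub-pixel half-contrast isophote around the detected pod component,
    which removes the outward half-pixel bias of the binary boundary.  If
    ``px_per_cm`` is given the marker search is skipped and the manual
    scale is used (for pre-calibrated rigs).
    """
    gray = _to_gray(image)
    if px_per_cm is not None:
        scale = ScaleCalibration.from_px_per_cm(px_per_cm, marker_cm)
    else:
        scale = detect_marker(gray, marker_cm)
    smoothed = gaussian_filter(gray, sigma)
    edges = canny_edges(smoothed, canny_low, canny_high)
    closed = morph_close(edges, close_radius)
    mask = _select_pod_mask(closed, min_area=min_area, exclude_marker=True)
    contour = _refine_contour(mask, smoothed) if refine else None
    if contour is None:
        rings = measure.find_contours(mask.astype(float), 0.5)
        pts = max(rings, key=len)[:, ::-1]
        contour = Contour(points=pts)
    if not contour.as_polygon().is_valid:
        warnings.warn("extracted contour is not a simple polygon", stacklevel=2)
    return contour, scale
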