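"""Shared fixtures: synthetic pods, dense geometric contours, scales."""

import numpy as np
import pytest

from podpheno.preprocessing import Contour, ScaleCalibration
from podpheno.synthetic import PodShapeSpec, generate_pod_image


@pytest.fixture(scope="session")
def default_pod():
    """Straight capsule at Table-4-like means: image, analytic truth, contour."""
    spec = PodShapeSpec()
    image, truth, contour = generate_pod_image(spec)
    return spec, image, truth, contour


@pytest.fixture(scope="session")
def scale50() -> ScaleCalibration:
    return ScaleCalibration.from_px_per_cm(50.0)


def dense_rectangle(x0: float, y0: float, x1: float, y1: float, step: float = 1.0) -> Contour:
    """Rectangle boundary sampled every ``step`` px (dense, CCW)."""
    xs = np.arange(x0, x1, step)
    ys = np.arange(y0, y1, step)
    top = np.column_stack([xs, np.full_like(xs, y0)])
    right = np.column_stack([np.full_like(ys, x1), ys])
    bottom = np.column_stack([xs[::-1] + step, np.full_like(xs, y1)])
    left = np.column_stack([np.full_like(ys, x0), ys[::-1] + step])
    return Contour(points=np.vstack([top, right, bottom, left]))


def dense_circle(cx: float, cy: float, r: float, n: int = 720) -> Contour:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return Contour(points=np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)]))


def semicircular_band(cx: float, cy: float, r_outer: float, r_inner: float, n: int = 360) -> Contour:
    """Half-annulus from angle 0 to pi (flat side down), dense boundary."""
    t = np.linspace(0.0, np.pi, n)
    outer = np.column_stack([cx + r_outer * np.cos(t), cy - r_outer * np.sin(t)])
    inner = np.column_stack([cx + r_inner * np.cos(t[::-1]), cy - r_inner * np.sin(t[::-1])])
    return Contour(points=np.vstack([outer, inner]))
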