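"""Axis-aligned bounding boxes and box-regression losses.

The box is the unit of every overlap, matching and loss computation in this
package: detection quality is scored by intersection-over-union (IOU), and
the bounding-box regression losses used by single-stage detectors are pure
functions of two boxes.  Three quantities are implemented:

* ``iou`` — the ratio of intersection to union area,
* ``giou`` — generalized IOU, which subtracts the fraction of the smallest
  enclosing rectangle not covered by the union, so that disjoint boxes are
  still ranked by proximity (values in (-1, 1]),
* ``eiou_loss`` — the extended-IOU loss, the sum of an overlap term
  ``1 - IOU``, a normalized squared center distance, and separate width and
  height mismatch terms.  Unlike the GIOU loss it keeps a usable width/height
  gradient when one box contains the other.

Boxes use continuous coordinates: area is ``(x2 - x1) * (y2 - y1)`` with no
+1 pixel convention, matching the loss formulas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "Box",
    "BoxPairGeometry",
    "iou",
    "giou",
    "giou_loss",
    "eiou_loss",
    "pair_geometry",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned box ``(x1, y1) .. (x2, y2)`` with optional confidence."""

    x1: float
    y1: float
    x2: float
    y2: float
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.x2 < self.x1 or self.y2 < self.y1:
            raise ValueError(
                f"box corners out of order: ({self.x1}, {self.y1}, {self.x2}, {self.y2})"
            )
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def w(self) -> float:
        return self.x2 - self.x1

    @property
    def h(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    def is_degenerate(self) -> bool:
        return self.w == 0.0 or self.h == 0.0


@dataclass(frozen=True)
class BoxPairGeometry:
    """Shared geometry of a (prediction, ground-truth) box pair.

    ``J``/``U`` are intersection and union areas, ``A`` the area of the
    smallest rectangle enclosing both boxes, ``rho2_center`` the squared
    distance between box centers, ``cw``/``ch`` the enclosing rectangle's
    width and height and ``c2 = cw**2 + ch**2`` its squared diagonal.
    """

    J: float
    U: float
    A: float
    rho2_center: float
    c2: float
    cw: float
    ch: float


def _intersection(a: Box, b: Box) -> float:
    iw = min(a.x2, b.x2) - max(a.x1, b.x1)
    ih = min(a.y2, b.y2) - max(a.y1, b.y1)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    return iw * ih


def pair_geometry(a: Box, b: Box) -> BoxPairGeometry:
    """Compute all shared pair quantities once."""
    J = _intersection(a, b)
    U = a.area + b.area - J
    cw = max(a.x2, b.x2) - min(a.x1, b.x1)
    ch = max(a.y2, b.y2) - min(a.y1, b.y1)
    (ax, ay), (bx, by) = a.center, b.center
    return BoxPairGeometry(
        J=J,
        U=U,
        A=cw * ch,
        rho2_center=(ax - bx) ** 2 + (ay - by) ** 2,
        c2=cw**2 + ch**2,
        cw=cw,
        ch=ch,
    )


def iou(a: Box, b: Box) -> float:
    """Intersection over union; 0 for degenerate boxes (with a warning)."""
    if a.is_degenerate() or b.is_degenerate():
        warnings.warn("degenerate box in IOU; returning 0", stacklevel=2)
        return 0.0
    g = pair_geometry(a, b)
    return g.J / g.U


def giou(a: Box, b: Box) -> float:
    """Generalized IOU: ``J/U - (A - U)/A``.

    Equals 1 iff the boxes coincide and approaches -1 as the boxes separate.
    """
    if a.is_degenerate() and b.is_degenerate():
        raise ValueError("GIOU undefined: both boxes degenerate")
    g = pair_geometry(a, b)
    iou_term = g.J / g.U if g.U > 0.0 else 0.0
    return iou_term - (g.A - g.U) / g.A


def giou_loss(pairs: list[tuple[Box, Box]]) -> float:
    """Localization loss ``sum(1 - GIOU)`` over matched (pred, gt) pairs.

    The pairing itself plays the role of the objectness indicator: only
    matched pairs contribute.
    """
    if not pairs:
        raise ValueError("giou_loss requires at least one (pred, gt) pair")
    return sum(1.0 - giou(p, g) for p, g in pairs)


def eiou_loss(pred: Box, gt: Box) -> float:
    """Extended-IOU loss: overlap + center-distance + width + height terms.

    ``1 - IOU + rho2(b, b_gt)/c2 + (w - w_gt)**2/cw**2 + (h - h_gt)**2/ch**2``
    where ``cw``/``ch``/``c2`` come from the smallest box enclosing both
    inputs.  Zero iff the boxes coincide; the width/height terms keep a
    non-zero gradient when one box strictly contains the other, where the
    GIOU penalty plateaus.
    """
    g = pair_geometry(pred, gt)
    if g.cw == 0.0 or g.ch == 0.0:
        raise ValueError("degenerate enclosing box: cw or ch is zero")
    iou_term = g.J / g.U if g.U > 0.0 else 0.0
    return (
        1.0
        - iou_term
        + g.rho2_center / g.c2
        + (pred.w - gt.w) ** 2 / g.cw**2
        + (pred.h - gt.h) ** 2 / g.ch**2
    )
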