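"""Coordinate-attention forward pass as a forward-only reference.

Coordinate attention factorizes channel attention into two 1-D poolings,
one along image height and one along width, so that the gating weights keep
positional information: a feature map ``x`` of shape (C, H, W) is pooled
into per-row aggregates ``Z^h`` (C, H) and per-column aggregates ``Z^w``
(C, W).  The two aggregates are concatenated along the spatial axis, passed
through a shared channel-reducing 1x1 convolution ``F1`` and a nonlinearity,
split back into the two directions, expanded to the original channel count
by 1x1 convolutions ``F_h``/``F_w``, and squashed by a sigmoid into row and
column gates ``g^h``/``g^w``.  The output re-weights the input::

    y[c, i, j] = x[c, i, j] * g^h[c, i] * g^w[c, j]

These are reference implementations in plain numpy — no batching, no
training machinery; gradients are only ever probed by finite differences in
the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CAWeights", "ca_pool", "ca_forward"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


@dataclass
class CAWeights:
    """Parameters of the coordinate-attention block for C channels.

    1x1 convolutions over a (C, L) map are plain matrix multiplies on the
    channel axis: ``F1`` maps C -> C/r, ``F_h`` and ``F_w`` map C/r -> C.
    Weights are drawn uniform(-0.5, 0.5) from ``seed``; C must be divisible
    by ``reduction_ratio``.
    """

    channels: int
    reduction_ratio: int = 2
    seed: int = 0
    w1: np.ndarray = field(init=False, repr=False)
    b1: np.ndarray = field(init=False, repr=False)
    wh: np.ndarray = field(init=False, repr=False)
    bh: np.ndarray = field(init=False, repr=False)
    ww: np.ndarray = field(init=False, repr=False)
    bw: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.channels % self.reduction_ratio != 0:
            raise ValueError(
                f"channels {self.channels} not divisible by "
                f"reduction_ratio {self.reduction_ratio}"
            )
        c, r = self.channels, self.reduction_ratio
        cr = c // r
        rng = np.random.default_rng(self.seed)
        self.w1 = rng.uniform(-0.5, 0.5, size=(cr, c))
        self.b1 = rng.uniform(-0.5, 0.5, size=cr)
        self.wh = rng.uniform(-0.5, 0.5, size=(c, cr))
        self.bh = rng.uniform(-0.5, 0.5, size=c)
        self.ww = rng.uniform(-0.5, 0.5, size=(c, cr))
        self.bw = rng.uniform(-0.5, 0.5, size=c)


def ca_pool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Directional average pooling of a (C, H, W) feature map.

    Returns ``Z^h`` of shape (C, H) — each row averaged over columns — and
    ``Z^w`` of shape (C, W) — each column averaged over rows.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError(f"expected (C, H, W) feature map, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite values")
    return x.mean(axis=2), x.mean(axis=1)


def ca_forward(x: np.ndarray, params: CAWeights) -> np.ndarray:
    """Coordinate-attention forward pass; output shape equals input shape."""
    x = np.asarray(x, dtype=float)
    zh, zw = ca_pool(x)  # (C, H), (C, W)
    c, h = zh.shape
    if c != params.channels:
        raise ValueError(
            f"feature map has {c} channels but weights expect {params.channels}"
        )
    z = np.concatenate([zh, zw], axis=1)  # (C, H + W)
    f = _relu(params.w1 @ z + params.b1[:, None])  # (C/r, H + W)
    fh, fw = f[:, :h], f[:, h:]
    gh = _sigmoid(params.wh @ fh + params.bh[:, None])  # (C, H)
    gw = _sigmoid(params.ww @ fw + params.bw[:, None])  # (C, W)
    return x * gh[:, :, None] * gw[:, None, :]
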