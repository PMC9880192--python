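"""Single-pod weight estimation with a 5-120-1 BP network, and yield totals.

Five pod traits — length, width, area, chord length and convex arc length —
predict the weight of a single pod through a fully connected feed-forward
network with 5 inputs, 120 sigmoid hidden units and one linear output,
trained by full-batch error backpropagation on min-max normalized inputs
and targets.  Training stops when the mean squared error on normalized
targets drops to the target accuracy (0.01 by default) or the epoch budget
runs out.  The learning rate follows a cost-guarded warm-up: it starts at
0.01 and grows while the training cost keeps falling, up to a ceiling of
0.8, backing off whenever the cost rises; a fixed-rate mode is also
available.

Per-plant yield is the product of the estimated mean single-pod weight and
the detected number of pods per plant; totals over a set of plants are the
per-plant weight times an explicit plant-count/scale factor.  Agreement
statistics are the per-item relative error ``p_i = |x_i - x̄_i| / x̄_i``,
the average absolute error AE, the average relative error RE, the MSE and
the coefficient of determination R².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TRAIT_COLUMNS",
    "BPModel",
    "ErrorStats",
    "PlantYieldEstimate",
    "bp_train",
    "bp_predict",
    "error_stats",
    "estimate_plant_weight",
    "estimate_total_weight",
    "relative_error",
]

TRAIT_COLUMNS = ["length_cm", "width_cm", "area_cm2", "chord_cm", "arc_cm"]

N_INPUT, N_HIDDEN, N_OUTPUT = 5, 120, 1


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class BPModel:
    """5-120-1 backpropagation network with min-max normalization.

    ``w1``/``b1`` map normalized traits to the hidden layer (sigmoid),
    ``w2``/``b2`` map the hidden layer to the normalized weight (identity).
    ``x_low``/``x_high`` and ``y_low``/``y_high`` are the normalization
    bounds learned from the training data.
    """

    learning_rate: float = 0.8
    lr_schedule: str = "warmup"  # cost-guarded growth from 0.01; or "fixed"
    target_mse: float = 0.01
    max_epochs: int = 3000
    seed: int = 0
    trained: bool = field(default=False, repr=False)
    w1: np.ndarray | None = field(default=None, repr=False)
    b1: np.ndarray | None = field(default=None, repr=False)
    w2: np.ndarray | None = field(default=None, repr=False)
    b2: np.ndarray | None = field(default=None, repr=False)
    x_low: np.ndarray | None = field(default=None, repr=False)
    x_high: np.ndarray | None = field(default=None, repr=False)
    y_low: float = field(default=0.0, repr=False)
    y_high: float = field(default=1.0, repr=False)
    final_mse: float = field(default=float("nan"), repr=False)
    epochs_run: int = field(default=0, repr=False)
    loss_history: list[float] = field(default_factory=list, repr=False)

    # -- persistence ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        if not self.trained:
            raise ValueError("cannot serialize an untrained model")
        payload = {
            "layers": [N_INPUT, N_HIDDEN, N_OUTPUT],
            "learning_rate": self.learning_rate,
            "lr_schedule": self.lr_schedule,
            "target_mse": self.target_mse,
            "max_epochs": self.max_epochs,
            "seed": self.seed,
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "x_low": self.x_low.tolist(),
            "x_high": self.x_high.tolist(),
            "y_low": self.y_low,
            "y_high": self.y_high,
            "final_mse": self.final_mse,
            "epochs_run": self.epochs_run,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "BPModel":
        d = json.loads(Path(path).read_text())
        if d["layers"] != [N_INPUT, N_HIDDEN, N_OUTPUT]:
            raise ValueError(f"unexpected layer sizes {d['layers']}")
        m = cls(
            learning_rate=d["learning_rate"],
            lr_schedule=d["lr_schedule"],
            target_mse=d["target_mse"],
            max_epochs=d["max_epochs"],
            seed=d["seed"],
        )
        m.w1 = np.asarray(d["w1"])
        m.b1 = np.asarray(d["b1"])
        m.w2 = np.asarray(d["w2"])
        m.b2 = np.asarray(d["b2"])
        m.x_low = np.asarray(d["x_low"])
        m.x_high = np.asarray(d["x_high"])
        m.y_low, m.y_high = d["y_low"], d["y_high"]
        m.final_mse = d["final_mse"]
        m.epochs_run = d["epochs_run"]
        m.trained = True
        return m


def _extract_xy(data: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        missing = [c for c in TRAIT_COLUMNS + ["weight_g"] if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        x = data[TRAIT_COLUMNS].to_numpy(dtype=float)
        y = data["weight_g"].to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 6:
            raise ValueError("expected an (n, 6) array of five traits + weight")
        x, y = arr[:, :5], arr[:, 5]
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")
    return x, y


class _WarmupSchedule:
    """Cost-guarded learning-rate warm-up ("bold driver").

    Starts at 0.01 and grows by 5% after every epoch whose training cost
    improved, up to the configured ceiling (0.8 by default); an epoch whose
    cost increased halves the rate.  The rate thus climbs while the descent
    is stable and settles just under the curvature-stability bound.
    """

    def __init__(self, ceiling: float, start: float = 0.01):
        self.lr = min(start, ceiling)
        self.ceiling = ceiling
        self._prev_cost: float | None = None

    def update(self, epoch: int, cost: float) -> float:
        if self._prev_cost is not None:
            if cost <= self._prev_cost:
                self.lr = min(self.lr * 1.05, self.ceiling)
            else:
                self.lr = max(self.lr * 0.5, 1e-4)
        self._prev_cost = cost
        return self.lr


def bp_train(
    data: pd.DataFrame | np.ndarray, config: BPModel | None = None
) -> BPModel:
    """Train the 5-120-1 network by full-batch gradient descent.

    ``data`` is a trait/weight table (columns ``length_cm, width_cm,
    area_cm2, chord_cm, arc_cm, weight_g`` or an (n, 6) array).  Training
    minimizes the MSE on normalized targets and stops at ``target_mse`` or
    ``max_epochs``.  Deterministic given the config seed.
    """
    m = config if config is not None else BPModel()
    x, y = _extract_xy(data)
    n = len(y)
    if n < 10:
        raise ValueError(f"need at least 10 training rows, got {n}")

    m.x_low = x.min(axis=0)
    m.x_high = x.max(axis=0)
    span = np.where(m.x_high > m.x_low, m.x_high - m.x_low, 1.0)
    xn = (x - m.x_low) / span
    m.y_low, m.y_high = float(y.min()), float(y.max())
    if m.y_high == m.y_low:
        # degenerate constant target: the exact fit needs no training
        m.w1 = np.zeros((N_INPUT, N_HIDDEN))
        m.b1 = np.zeros(N_HIDDEN)
        m.w2 = np.zeros((N_HIDDEN, N_OUTPUT))
        m.b2 = np.zeros(N_OUTPUT)
        m.final_mse = 0.0
        m.epochs_run = 0
        m.loss_history = [0.0]
        m.trained = True
        return m
    yspan = m.y_high - m.y_low
    yn = (y - m.y_low) / yspan

    rng = np.random.default_rng(m.seed)
    w1 = rng.uniform(-0.5, 0.5, size=(N_INPUT, N_HIDDEN))
    b1 = rng.uniform(-0.5, 0.5, size=N_HIDDEN)
    w2 = rng.uniform(-0.5, 0.5, size=(N_HIDDEN, N_OUTPUT))
    b2 = rng.uniform(-0.5, 0.5, size=N_OUTPUT)

    if m.lr_schedule == "warmup":
        schedule = _WarmupSchedule(ceiling=m.learning_rate)
    elif m.lr_schedule == "fixed":
        schedule = None
    else:
        raise ValueError(f"unknown lr_schedule {m.lr_schedule!r}")

    m.loss_history = []
    mse = float("inf")
    epoch = 0
    for epoch in range(m.max_epochs):
        hidden = _sigmoid(xn @ w1 + b1)  # (n, 120)
        pred = (hidden @ w2 + b2).ravel()  # (n,)
        err = pred - yn
        mse = float(np.mean(err**2))
        if not np.isfinite(mse):
            raise FloatingPointError(
                f"training diverged (non-finite loss) at epoch {epoch}"
            )
        m.loss_history.append(mse)
        if mse <= m.target_mse:
            break
        lr = m.learning_rate if schedule is None else schedule.update(epoch, mse)
        # backprop of mean squared error, full batch
        d_out = 2.0 * err[:, None] / n  # (n, 1)
        g_w2 = hidden.T @ d_out
        g_b2 = d_out.sum(axis=0)
        d_hidden = (d_out @ w2.T) * hidden * (1.0 - hidden)  # (n, 120)
        g_w1 = xn.T @ d_hidden
        g_b1 = d_hidden.sum(axis=0)
        w2 -= lr * g_w2
        b2 -= lr * g_b2
        w1 -= lr * g_w1
        b1 -= lr * g_b1

    m.w1, m.b1, m.w2, m.b2 = w1, b1, w2, b2
    m.final_mse = mse
    m.epochs_run = epoch + 1
    m.trained = True
    return m


def bp_predict(model: BPModel, traits: np.ndarray | list[float]) -> np.ndarray | float:
    """Predict pod weight in grams from a 5-vector (or (n, 5) array) of traits.

    Traits far outside the normalization bounds (beyond ±50% of the trained
    span) trigger a warning but are still evaluated.
    """
    if not model.trained:
        raise ValueError("model has not been trained")
    t = np.atleast_2d(np.asarray(traits, dtype=float))
    if t.shape[1] != N_INPUT:
        raise ValueError(f"expected 5 traits, got shape {t.shape}")
    span = np.where(model.x_high > model.x_low, model.x_high - model.x_low, 1.0)
    tn = (t - model.x_low) / span
    if np.any(tn < -0.5) or np.any(tn > 1.5):
        import warnings

        warnings.warn(
            "traits outside +/-50% of the training normalization bounds",
            stacklevel=2,
        )
    hidden = _sigmoid(tn @ model.w1 + model.b1)
    yn = (hidden @ model.w2 + model.b2).ravel()
    yspan = model.y_high - model.y_low if model.y_high > model.y_low else 1.0
    y = yn * yspan + model.y_low
    return float(y[0]) if np.ndim(traits) == 1 else y


# -- agreement statistics --------------------------------------------------


@dataclass(frozen=True)
class ErrorStats:
    """Agreement between predicted and measured values."""

    relative_errors: tuple[float, ...]  # p_i = |x_i - x̄_i| / x̄_i
    AE: float  # mean absolute error
    RE: float  # mean relative error
    MSE: float
    r2: float


def error_stats(predicted, measured) -> ErrorStats:
    """Relative/absolute error statistics of predictions against measurements."""
    x = np.asarray(predicted, dtype=float)
    xbar = np.asarray(measured, dtype=float)
    if x.shape != xbar.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("predicted and measured must be equal-length 1-D vectors")
    if np.any(xbar == 0.0):
        raise ValueError("measured value of 0: relative error undefined")
    abs_err = np.abs(x - xbar)
    p = abs_err / np.abs(xbar)
    ss_res = float(np.sum((x - xbar) ** 2))
    ss_tot = float(np.sum((xbar - xbar.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0.0 else (1.0 if ss_res == 0.0 else 0.0)
    return ErrorStats(
        relative_errors=tuple(p.tolist()),
        AE=float(abs_err.mean()),
        RE=float(p.mean()),
        MSE=float(np.mean((x - xbar) ** 2)),
        r2=r2,
    )


@dataclass(frozen=True)
class PlantYieldEstimate:
    """Yield roll-up from single-pod weight to a set of plants."""

    single_pod_weight_g: float
    pods_per_plant: int
    plant_weight_g: float
    total_weight_g: float | None = None


def estimate_plant_weight(single_pod_weight_g: float, pods_per_plant: int) -> float:
    """Per-plant pod weight: mean single-pod weight times pod count (3 d.p.)."""
    if single_pod_weight_g <= 0.0:
        raise ValueError("single pod weight must be positive")
    if pods_per_plant < 0:
        raise ValueError("pod count must be non-negative")
    return round(single_pod_weight_g * pods_per_plant, 3)


def estimate_total_weight(
    plant_weight_g: float,
    n_plants_or_scale: float,
    measured_total_g: float | None = None,
) -> tuple[float, float | None]:
    """Total pod weight over a set of plants, and its relative error.

    ``n_plants_or_scale`` is the explicit plant count (or fractional scale)
    the per-plant weight is extrapolated by.  If a measured total is given,
    the relative error ``|pred - measured| / measured`` is returned with it.
    """
    if plant_weight_g <= 0.0 or n_plants_or_scale <= 0.0:
        raise ValueError("plant weight and scale must be positive")
    total = plant_weight_g * n_plants_or_scale
    rel = None
    if measured_total_g is not None:
        if measured_total_g == 0.0:
            raise ValueError("measured total of 0: relative error undefined")
        rel = abs(total - measured_total_g) / abs(measured_total_g)
    return total, rel


def relative_error(predicted_total_g: float, measured_total_g: float) -> float:
    """Relative error of a total-yield prediction against the measured total."""
    if measured_total_g == 0.0:
        raise ValueError("measured total of 0: relative error undefined")
    return abs(predicted_total_g - measured_total_g) / abs(measured_total_g)
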