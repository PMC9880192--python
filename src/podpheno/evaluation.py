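"""Detection evaluation: TP/FP matching, precision/recall, PR curve and AP.

The matching protocol scores a detector's output against hand-labelled
ground truth.  Predictions whose confidence does not exceed a retention
threshold (0.3 by default) are discarded; the rest are processed in strictly
descending confidence (ties broken by input order).  Each prediction claims
its maximum-IOU ground-truth box; if that IOU exceeds the IOU threshold
(0.5 by default) and the ground truth has not been matched before, the
prediction is a true positive — otherwise (low overlap, or a duplicate hit
on an already-matched box) it is a false positive.  Ground-truth boxes left
unmatched are false negatives.

Precision P = TP/(TP+FP) and recall R = TP/(TP+FN).  The average precision
(AP) is the area under the precision-recall curve swept over the confidence
threshold; with a single target class mAP equals AP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boxes import Box, iou

__all__ = [
    "MatchCounts",
    "PRCurve",
    "match_detections",
    "precision_recall",
    "format_percent",
    "pr_curve",
    "count_table",
    "count_difference",
]

DEFAULT_CONF_THRESH = 0.3
DEFAULT_IOU_THRESH = 0.5


@dataclass(frozen=True)
class MatchCounts:
    """True/false positive and false negative counts for one box set."""

    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("negative match count")

    @property
    def n_gt(self) -> int:
        return self.TP + self.FN

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.TP + other.TP, self.FP + other.FP, self.FN + other.FN)


@dataclass(frozen=True)
class PRCurve:
    """Precision-recall points swept over confidence, with the AP value."""

    recall: tuple[float, ...]
    precision: tuple[float, ...]
    ap: float
    method: str = "envelope"

    @property
    def map(self) -> float:
        # single-class evaluation: mAP is AP
        return self.ap


def _as_scored_preds(
    preds: list[tuple[Box, float] | Box],
) -> list[tuple[Box, float]]:
    out: list[tuple[Box, float]] = []
    for p in preds:
        if isinstance(p, Box):
            if p.confidence is None:
                raise ValueError("prediction box without confidence")
            out.append((p, p.confidence))
        else:
            box, conf = p
            out.append((box, float(conf)))
    return out


def _greedy_match(
    gt: list[Box], kept: list[tuple[Box, float]], iou_thresh: float
) -> MatchCounts:
    """Descending-confidence greedy matching of retained predictions."""
    order = sorted(range(len(kept)), key=lambda i: -kept[i][1])
    matched = [False] * len(gt)
    tp = fp = 0
    for i in order:
        box = kept[i][0]
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gt):
            v = iou(box, g)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou > iou_thresh and not matched[best_j]:
            matched[best_j] = True
            tp += 1
        else:
            fp += 1
    return MatchCounts(TP=tp, FP=fp, FN=matched.count(False))


def match_detections(
    gt: list[Box],
    preds: list[tuple[Box, float] | Box],
    conf_thresh: float = DEFAULT_CONF_THRESH,
    iou_thresh: float = DEFAULT_IOU_THRESH,
) -> MatchCounts:
    """Match predictions to ground truth and count TP/FP/FN.

    Both thresholds are strict: a prediction is retained only if its
    confidence is greater than ``conf_thresh``, and counts as a hit only if
    its best IOU is greater than ``iou_thresh`` against a ground-truth box
    matched for the first time.
    """
    scored = _as_scored_preds(preds)
    kept = [(b, c) for b, c in scored if c > conf_thresh]
    return _greedy_match(list(gt), kept, iou_thresh)


def precision_recall(counts: MatchCounts) -> tuple[float, float]:
    """Precision and recall as fractions; zero denominators give 0."""
    if counts.TP + counts.FP == 0:
        warnings.warn("no retained predictions: precision defined as 0", stacklevel=2)
        p = 0.0
    else:
        p = counts.TP / (counts.TP + counts.FP)
    if counts.TP + counts.FN == 0:
        warnings.warn("no ground-truth boxes: recall defined as 0", stacklevel=2)
        r = 0.0
    else:
        r = counts.TP / (counts.TP + counts.FN)
    return p, r


def format_percent(fraction: float, decimals: int = 0) -> float:
    """Report a fraction as a percentage rounded to ``decimals`` places."""
    return round(fraction * 100.0, decimals) if decimals else round(fraction * 100.0)


def pr_curve(
    gt_sets: list[list[Box]],
    pred_sets: list[list[tuple[Box, float] | Box]],
    iou_thresh: float = DEFAULT_IOU_THRESH,
    ap_method: str = "envelope",
) -> PRCurve:
    """Sweep the confidence threshold and integrate the PR curve.

    Each element of ``gt_sets``/``pred_sets`` is one image; matching never
    crosses images.  At every distinct prediction score ``s`` the full
    matching is recomputed keeping predictions with confidence >= s, giving
    one (recall, precision) point.  ``ap_method`` selects the integration
    rule: ``envelope`` (area under the monotone precision envelope,
    all-point interpolation) or ``trapezoid`` (raw trapezoidal area).
    """
    if len(gt_sets) != len(pred_sets):
        raise ValueError("gt_sets and pred_sets differ in length")
    scored_sets = [_as_scored_preds(p) for p in pred_sets]
    n_gt = sum(len(g) for g in gt_sets)
    if n_gt == 0:
        raise ValueError("pr_curve requires at least one ground-truth box")
    scores = sorted({c for preds in scored_sets for _, c in preds}, reverse=True)
    if not scores:
        return PRCurve(recall=(0.0,), precision=(0.0,), ap=0.0, method=ap_method)

    recalls, precisions = [], []
    for s in scores:
        total = MatchCounts(0, 0, 0)
        for gt, preds in zip(gt_sets, scored_sets):
            kept = [(b, c) for b, c in preds if c >= s]
            total = total + _greedy_match(list(gt), kept, iou_thresh)
        p, r = precision_recall(total) if total.TP + total.FP else (1.0, 0.0)
        recalls.append(r)
        precisions.append(p)

    rec = np.asarray(recalls)
    prec = np.asarray(precisions)
    order = np.argsort(rec, kind="stable")
    rec, prec = rec[order], prec[order]

    if ap_method == "envelope":
        env = np.maximum.accumulate(prec[::-1])[::-1]
        r_prev = 0.0
        ap = 0.0
        for r, p in zip(rec, env):
            ap += (r - r_prev) * p
            r_prev = r
    elif ap_method == "trapezoid":
        rs = np.concatenate([[0.0], rec])
        ps = np.concatenate([[prec[0]], prec])
        ap = float(np.trapezoid(ps, rs))
    else:
        raise ValueError(f"unknown ap_method {ap_method!r}")
    return PRCurve(
        recall=tuple(rec.tolist()),
        precision=tuple(prec.tolist()),
        ap=float(ap),
        method=ap_method,
    )


def count_table(
    per_stage_results: dict[str, dict[str, MatchCounts | tuple[int, int]]],
) -> pd.DataFrame:
    """Tabulate TP and FP by model (rows) and growth stage (columns).

    ``per_stage_results`` maps model name -> stage label -> MatchCounts (or
    a raw (TP, FP) pair).  All models must report the same stages.
    """
    models = list(per_stage_results)
    if not models:
        raise ValueError("no models given")
    stages = list(per_stage_results[models[0]])
    for m in models[1:]:
        if list(per_stage_results[m]) != stages:
            raise ValueError(
                f"stage labels of {m!r} do not match {models[0]!r}: "
                f"{list(per_stage_results[m])} vs {stages}"
            )
    rows = {}
    for m in models:
        tp_row, fp_row = {}, {}
        for s in stages:
            c = per_stage_results[m][s]
            tp, fp = (c.TP, c.FP) if isinstance(c, MatchCounts) else c
            tp_row[s], fp_row[s] = tp, fp
        rows[(m, "TP")] = tp_row
        rows[(m, "FP")] = fp_row
    table = pd.DataFrame(rows).T
    table.index = pd.MultiIndex.from_tuples(table.index, names=["model", "count"])
    return table


def count_difference(
    table: pd.DataFrame, model_a: str, model_b: str
) -> pd.DataFrame:
    """Per-stage TP and FP differences ``model_a - model_b``."""
    for m in (model_a, model_b):
        if m not in table.index.get_level_values("model"):
            raise ValueError(f"model {m!r} not in table")
    return table.loc[model_a] - table.loc[model_b]
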