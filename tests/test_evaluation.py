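"""Matching protocol, precision/recall, PR sweep and stage tables."""

import itertools

import numpy as np
import pytest

from podpheno.boxes import Box
from podpheno.evaluation import (
    MatchCounts,
    count_difference,
    count_table,
    format_percent,
    match_detections,
    pr_curve,
    precision_recall,
)
from podpheno.synthetic import generate_detection_scene


def shapely_iou(a: Box, b: Box) -> float:
    """Independent IOU via polygon intersection."""
    from shapely.geometry import box as sbox

    pa, pb = sbox(a.x1, a.y1, a.x2, a.y2), sbox(b.x1, b.y1, b.x2, b.y2)
    u = pa.union(pb).area
    return pa.intersection(pb).area / u if u else 0.0


def first_match_counts(gt, scored_preds, order, conf_thresh=0.3, iou_thresh=0.5):
    """Naive first-match rule applied in an explicit processing order."""
    kept = [(b, c) for b, c in scored_preds if c > conf_thresh]
    matched = set()
    tp = fp = 0
    for i in order:
        if i >= len(kept):
            continue
        box = kept[i][0]
        ious = [shapely_iou(box, g) for g in gt]
        j = int(np.argmax(ious)) if ious else -1
        if j >= 0 and ious[j] > iou_thresh and j not in matched:
            matched.add(j)
            tp += 1
        else:
            fp += 1
    return tp, fp, len(gt) - len(matched)


class TestMatching:
    def test_perfect_detector(self):
        gt = [Box(10 * i, 0, 10 * i + 8, 8) for i in range(3)]
        preds = [(g, 0.9) for g in gt]
        c = match_detections(gt, preds)
        assert (c.TP, c.FP, c.FN) == (3, 0, 0)

    def test_duplicate_is_false_positive(self):
        # matched "for the first time" -> the second identical hit is FP
        gt = [Box(0, 0, 10, 10)]
        preds = [(Box(0, 0, 10, 10), 0.9), (Box(0, 0, 10, 10), 0.8)]
        c = match_detections(gt, preds)
        assert (c.TP, c.FP, c.FN) == (1, 1, 0)

    def test_confidence_retention_is_strict(self):
        gt = [Box(0, 0, 10, 10)]
        c = match_detections(gt, [(Box(0, 0, 10, 10), 0.25)])
        assert (c.TP, c.FP, c.FN) == (0, 0, 1)
        c = match_detections(gt, [(Box(0, 0, 10, 10), 0.3)])  # not > 0.3
        assert (c.TP, c.FP, c.FN) == (0, 0, 1)

    def test_empty_inputs_yield_zero_counts(self):
        c = match_detections([], [])
        assert (c.TP, c.FP, c.FN) == (0, 0, 0)

    def test_greedy_equals_bruteforce_on_small_instances(self):
        """On every fixture with <= 6 boxes the descending-confidence
        result equals the naive first-match oracle applied in that order,
        enumerated against all other orders for sanity."""
        rng = np.random.default_rng(42)
        for trial in range(12):
            n_gt = int(rng.integers(1, 4))
            n_pred = int(rng.integers(1, 4))
            gt = [Box(x, y, x + 10, y + 10) for x, y in rng.uniform(0, 40, (n_gt, 2))]
            scored = [
                (Box(x, y, x + 10, y + 10), float(c))
                for (x, y), c in zip(
                    rng.uniform(0, 40, (n_pred, 2)), rng.uniform(0.31, 0.99, n_pred)
                )
            ]
            c = match_detections(gt, scored)
            kept = sorted(range(len(scored)), key=lambda i: -scored[i][1])
            assert (c.TP, c.FP, c.FN) == first_match_counts(gt, scored, kept)
            # all orderings conserve TP + FP (= retained predictions)
            for order in itertools.permutations(range(len(scored))):
                tp, fp, _ = first_match_counts(gt, scored, list(order))
                assert tp + fp == c.TP + c.FP

    def test_scene_generator_counts_match_construction(self):
        sc = generate_detection_scene(n_gt=5, n_dup=2, n_spurious=3, seed=0)
        c = match_detections(list(sc.gt_boxes), list(sc.predictions))
        assert (c.TP, c.FP) == (5, 5)

    def test_threshold_monotonicity(self):
        sc = generate_detection_scene(n_gt=8, n_dup=3, n_spurious=4, seed=1)
        gt, preds = list(sc.gt_boxes), list(sc.predictions)
        prev = None
        for t in np.linspace(0.0, 1.0, 21):
            c = match_detections(gt, preds, conf_thresh=float(t))
            if prev is not None:
                assert c.TP <= prev.TP
                assert c.FN >= prev.FN
            prev = c


class TestPrecisionRecall:
    def test_study_recall_examples(self):
        p, r = precision_recall(MatchCounts(TP=22, FP=0, FN=1))
        assert format_percent(r) == 96
        p, r = precision_recall(MatchCounts(TP=14, FP=0, FN=3))
        assert format_percent(r, 1) == 82.4

    def test_degenerate_counts_give_zero_with_warning(self):
        with pytest.warns(UserWarning):
            p, r = precision_recall(MatchCounts(TP=0, FP=0, FN=5))
        assert (p, r) == (0.0, 0.0)


class TestPRCurve:
    def test_perfect_detector_ap_is_one(self):
        gt = [Box(20 * i, 0, 20 * i + 10, 10) for i in range(4)]
        preds = [(g, 0.5 + 0.1 * i) for i, g in enumerate(gt)]
        assert pr_curve([gt], [preds]).ap == pytest.approx(1.0)

    def test_half_recall_rectangle(self):
        # detector finds exactly half the pods with perfect precision
        gt = [Box(20 * i, 0, 20 * i + 10, 10) for i in range(4)]
        preds = [(gt[0], 0.9), (gt[1], 0.8)]
        curve = pr_curve([gt], [preds])
        assert curve.ap == pytest.approx(0.5)

    def test_single_class_map_equals_ap(self):
        sc = generate_detection_scene(n_gt=6, n_dup=2, n_spurious=2, seed=3)
        curve = pr_curve([list(sc.gt_boxes)], [list(sc.predictions)])
        assert curve.map == curve.ap

    def test_recall_nondecreasing_along_sweep(self):
        sc = generate_detection_scene(n_gt=6, n_dup=2, n_spurious=3, seed=4)
        curve = pr_curve([list(sc.gt_boxes)], [list(sc.predictions)])
        assert all(b >= a for a, b in zip(curve.recall, curve.recall[1:]))
        assert all(0.0 <= v <= 1.0 for v in curve.recall + curve.precision)

    def test_trapezoid_option(self):
        gt = [Box(20 * i, 0, 20 * i + 10, 10) for i in range(4)]
        preds = [(g, 0.5 + 0.1 * i) for i, g in enumerate(gt)]
        assert pr_curve([gt], [preds], ap_method="trapezoid").ap == pytest.approx(1.0)
        with pytest.raises(ValueError):
            pr_curve([gt], [preds], ap_method="simpson")


class TestCountTable:
    RESULTS = {
        "improved": {
            "R5": (1795, 336), "R6": (1851, 297), "R7": (1729, 266), "R8": (1704, 206),
        },
        "baseline": {
            "R5": (1708, 504), "R6": (1725, 378), "R7": (1707, 336), "R8": (1697, 227),
        },
    }

    def test_stage_table_shape_and_values(self):
        table = count_table(self.RESULTS)
        assert table.loc[("improved", "TP"), "R5"] == 1795
        assert table.loc[("baseline", "FP"), "R8"] == 227

    def test_model_differences(self):
        table = count_table(self.RESULTS)
        diff = count_difference(table, "improved", "baseline")
        assert list(diff.loc["TP"]) == [87, 126, 22, 7]
        fp_gap = -diff.loc["FP"]
        assert fp_gap.max() == 168 and fp_gap.idxmax() == "R5"

    def test_identical_models_give_zero_difference(self):
        table = count_table({"a": self.RESULTS["improved"], "b": self.RESULTS["improved"]})
        assert (count_difference(table, "a", "b") == 0).all().all()

    def test_mismatched_stages_raise(self):
        bad = {"a": {"R5": (1, 1)}, "b": {"R6": (1, 1)}}
        with pytest.raises(ValueError):
            count_table(bad)
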