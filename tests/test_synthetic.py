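"""Generators: analytic ground truth, determinism, augmentations."""

import numpy as np
import pytest

from podpheno.synthetic import (
    DEFAULT_TRAIT_MEANS,
    PodShapeSpec,
    YieldDatasetSpec,
    analytic_phenotype,
    augment,
    generate_detection_scene,
    generate_pod_image,
    generate_yield_dataset,
)
from podpheno.yield_model import TRAIT_COLUMNS


class TestPodImage:
    def test_table_mean_spec_has_stated_length_and_width(self):
        spec = PodShapeSpec(length_cm=4.56, width_cm=1.02, bend_angle_deg=0.0, seed=1)
        _, truth, _ = generate_pod_image(spec)
        assert truth.length_cm == 4.56
        assert truth.width_cm == 1.02

    def test_straight_capsule_chord_equals_length(self):
        truth = analytic_phenotype(PodShapeSpec(bend_angle_deg=0.0))
        assert truth.chord_cm == truth.length_cm

    def test_bent_capsule_chord_below_length_arc_above_chord(self):
        spec = PodShapeSpec(length_cm=5.0, width_cm=1.0, bend_angle_deg=30.0)
        truth = analytic_phenotype(spec)
        assert truth.chord_cm < 5.0
        assert truth.arc_cm > truth.chord_cm
        # centerline-polyline oracle for the chord: tips are the endpoints
        # of the generating arc pushed out by width/2 along the tangents
        theta = np.radians(30.0)
        rho = (5.0 - 1.0) / theta
        chord = 2 * (rho * np.sin(theta / 2) + 0.5 * np.cos(theta / 2))
        assert truth.chord_cm == pytest.approx(chord, rel=1e-12)

    def test_chord_to_arc_ratio_decreases_with_bend(self):
        ratios = [
            (lambda t: t.chord_cm / t.arc_cm)(
                analytic_phenotype(PodShapeSpec(bend_angle_deg=b))
            )
            for b in (0.0, 15.0, 30.0, 45.0)
        ]
        assert all(b < a for a, b in zip(ratios, ratios[1:]))

    def test_bit_identical_for_same_spec(self):
        a, _, _ = generate_pod_image(PodShapeSpec(seed=3))
        b, _, _ = generate_pod_image(PodShapeSpec(seed=3))
        np.testing.assert_array_equal(a, b)

    def test_image_contains_pod_and_marker_grays(self):
        img, _, _ = generate_pod_image(PodShapeSpec())
        assert set(np.unique(img)) == {10, 60, 230}
        marker_px = int(round(2.0 * 50.0))
        assert np.sum(img == 10) == marker_px**2  # exact marker pixel count

    def test_too_small_image_raises_with_dimension(self):
        with pytest.raises(ValueError, match="rows"):
            generate_pod_image(PodShapeSpec(image_size=(80, 560)))
        with pytest.raises(ValueError, match="cols"):
            generate_pod_image(PodShapeSpec(image_size=(420, 100)))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PodShapeSpec(length_cm=1.0, width_cm=1.5)
        with pytest.raises(ValueError):
            PodShapeSpec(bend_angle_deg=120.0)

    def test_rasterized_area_matches_analytic(self):
        spec = PodShapeSpec(seed=5)
        img, truth, _ = generate_pod_image(spec)
        pod_px = int(np.sum(img == 60))
        analytic_px = truth.area_cm2 * spec.px_per_cm**2
        assert pod_px == pytest.approx(analytic_px, rel=0.02)


class TestDetectionScene:
    def test_perfect_scene(self):
        from podpheno.evaluation import match_detections

        sc = generate_detection_scene(n_gt=5, n_dup=0, n_spurious=0, jitter_px=0.0, seed=1)
        c = match_detections(list(sc.gt_boxes), list(sc.predictions))
        assert (c.TP, c.FP, c.FN) == (5, 0, 0)

    def test_same_seed_identical(self):
        a = generate_detection_scene(4, 1, 2, seed=9)
        b = generate_detection_scene(4, 1, 2, seed=9)
        assert a == b

    def test_boxes_inside_image(self):
        sc = generate_detection_scene(6, 2, 3, seed=2)
        rows, cols = sc.image_size
        for b in sc.gt_boxes + tuple(p for p, _ in sc.predictions):
            assert 0 <= b.x1 <= b.x2 <= cols and 0 <= b.y1 <= b.y2 <= rows

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_detection_scene(-1)


class TestYieldDataset:
    def test_noiseless_is_exact_linear_map(self):
        spec = YieldDatasetSpec(n=50, noise_sd=0.0, seed=1)
        df = generate_yield_dataset(spec)
        expected = df[TRAIT_COLUMNS].to_numpy() @ np.asarray(spec.coeffs) + spec.intercept
        np.testing.assert_allclose(df["weight_g"], expected, atol=1e-12)

    def test_residual_sd_matches_noise(self):
        spec = YieldDatasetSpec(n=100, noise_sd=0.02, seed=2)
        df = generate_yield_dataset(spec)
        clean = df[TRAIT_COLUMNS].to_numpy() @ np.asarray(spec.coeffs) + spec.intercept
        sd = np.std(df["weight_g"] - clean)
        assert 0.01 <= sd <= 0.03

    def test_means_near_trait_table_when_ranges_centered_on_it(self):
        ranges = tuple((0.9 * m, 1.1 * m) for m in DEFAULT_TRAIT_MEANS)
        df = generate_yield_dataset(YieldDatasetSpec(n=400, trait_ranges=ranges, seed=3))
        means = df[TRAIT_COLUMNS].mean().to_numpy()
        np.testing.assert_allclose(means, DEFAULT_TRAIT_MEANS, rtol=0.05)

    def test_deterministic(self):
        a = generate_yield_dataset(YieldDatasetSpec(seed=4))
        b = generate_yield_dataset(YieldDatasetSpec(seed=4))
        assert a.equals(b)

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            YieldDatasetSpec(trait_ranges=((1, 0.5),) * 5)


class TestAugment:
    def test_rotate_zero_is_identity(self):
        img, _, _ = generate_pod_image(PodShapeSpec())
        np.testing.assert_array_equal(augment(img, "rotate", {"angle": 0.0}), img)

    def test_rotate_full_turn_is_identity(self):
        img, _, _ = generate_pod_image(PodShapeSpec())
        np.testing.assert_array_equal(augment(img, "rotate", {"angle": 360.0}), img)

    def test_rotate_preserves_shape(self):
        img, _, _ = generate_pod_image(PodShapeSpec())
        assert augment(img, "rotate", {"angle": 33.0}).shape == img.shape

    def test_gaussian_noise_sd(self):
        img = np.full((200, 200), 128, dtype=np.uint8)
        noisy = augment(img, "gaussian_noise", {"sd": 5.0}, seed=1)
        sd = float(np.std(noisy.astype(float)))
        assert abs(sd - 5.0) / 5.0 < 0.10

    def test_noise_deterministic_in_seed(self):
        img = np.full((50, 50), 100, dtype=np.uint8)
        a = augment(img, "gaussian_noise", {"sd": 3.0}, seed=7)
        b = augment(img, "gaussian_noise", {"sd": 3.0}, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_brightness_shift(self):
        img = np.full((10, 10), 100, dtype=np.uint8)
        assert np.all(augment(img, "brightness", {"delta": 20}) == 120)

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            augment(np.zeros((5, 5)), "shear")
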