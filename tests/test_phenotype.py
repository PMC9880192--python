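"""Trait calculators against analytic shapes and the generator oracle."""

import numpy as np
import pytest

from conftest import dense_circle, dense_rectangle, semicircular_band
from podpheno.phenotype import (
    PodPhenotype,
    chord_and_arc,
    measure,
    pod_area,
    pod_length,
    pod_width,
)
from podpheno.preprocessing import preprocess
from podpheno.synthetic import PodShapeSpec, generate_pod_image


def rotated_rect_contour(cx, cy, w, h, angle_deg, step=1.0):
    c = dense_rectangle(-w / 2, -h / 2, w / 2, h / 2, step)
    t = np.radians(angle_deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    from podpheno.preprocessing import Contour

    return Contour(points=c.points @ rot.T + [cx, cy])


class TestLength:
    def test_axis_aligned_rectangle(self, scale50):
        c = dense_rectangle(100, 100, 300, 140)  # 200 x 40 px
        assert pod_length(c, scale50) == pytest.approx(4.0, rel=1e-3)

    def test_rotation_invariant(self, scale50):
        base = pod_length(rotated_rect_contour(200, 200, 200, 40, 0.0), scale50)
        rot = pod_length(rotated_rect_contour(200, 200, 200, 40, 37.0), scale50)
        assert rot == pytest.approx(base, rel=0.01)

    def test_straight_capsule_recovers_generator_length(self):
        img, truth, _ = generate_pod_image(PodShapeSpec(length_cm=4.56, width_cm=1.02))
        contour, scale = preprocess(img)
        assert pod_length(contour, scale) == pytest.approx(4.56, rel=0.02)


class TestWidth:
    def test_circle_width_is_diameter(self, scale50):
        c = dense_circle(200, 200, 25)
        w, circle = pod_width(c, scale50)
        assert w == pytest.approx(1.0, rel=1e-3)
        assert circle.radius_px == pytest.approx(25, rel=1e-3)
        assert circle.area_px == pytest.approx(np.pi * 25**2, rel=1e-3)

    def test_rectangle_width_is_min_center_distance(self, scale50):
        c = dense_rectangle(100, 100, 300, 140)
        w, circle = pod_width(c, scale50)
        assert w == pytest.approx(0.8, rel=1e-2)  # 2 * 20 px / 50 px/cm
        assert circle.center == pytest.approx((200, 120), abs=1.0)

    def test_capsule_recovers_generator_width(self):
        img, _, _ = generate_pod_image(PodShapeSpec(length_cm=4.56, width_cm=1.02))
        contour, scale = preprocess(img)
        w, _ = pod_width(contour, scale)
        assert w == pytest.approx(1.02, rel=0.02)

    def test_centroid_rule_agrees_with_distance_transform(self):
        img, _, _ = generate_pod_image(PodShapeSpec(seed=2))
        contour, scale = preprocess(img)
        w1, _ = pod_width(contour, scale, method="centroid_min")
        w2, _ = pod_width(contour, scale, method="distance_transform")
        assert abs(w1 - w2) / w2 < 0.05

    def test_strongly_bent_shape_falls_back_with_warning(self, scale50):
        c = semicircular_band(300, 300, 120, 80)  # centroid in the hole
        with pytest.warns(UserWarning, match="centroid"):
            w, _ = pod_width(c, scale50)
        assert w == pytest.approx(2 * 20 / 50.0, rel=0.10)

    def test_unknown_method_rejected(self, scale50):
        with pytest.raises(ValueError):
            pod_width(dense_circle(50, 50, 20), scale50, method="bogus")


class TestArea:
    def test_template_calibration_arithmetic(self, scale50):
        # rectangle covering exactly 100 x 50 pixel centers = 5000 px
        c = dense_rectangle(9.5, 9.5, 109.5, 59.5)
        # marker: 10000 px for 4 cm2 (from_px_per_cm at 50)
        assert scale50.marker_px_area == 10000
        assert pod_area(c, scale50) == pytest.approx(5000 * 4.0 / 10000, rel=0.001)

    def test_circle_area(self, scale50):
        c = dense_circle(150, 150, 50)
        assert pod_area(c, scale50) == pytest.approx(np.pi, rel=0.02)

    def test_capsule_area_matches_stadium_formula(self):
        spec = PodShapeSpec(length_cm=5.0, width_cm=1.0)
        img, truth, _ = generate_pod_image(spec)
        contour, scale = preprocess(img)
        stadium = (5.0 - 1.0) * 1.0 + np.pi * 0.5**2
        assert truth.area_cm2 == pytest.approx(stadium, rel=1e-12)
        assert pod_area(contour, scale) == pytest.approx(stadium, rel=0.03)


class TestChordArc:
    def test_semicircular_band_chord_is_diameter(self, scale50):
        c = semicircular_band(300, 300, 60, 45)
        chord, arc, _ = chord_and_arc(c, scale50)
        assert chord == pytest.approx(2 * 60 / 50.0, rel=0.03)
        assert arc >= chord

    def test_straight_capsule_chord_equals_length(self):
        img, _, _ = generate_pod_image(PodShapeSpec())
        contour, scale = preprocess(img)
        chord, arc, _ = chord_and_arc(contour, scale)
        assert chord == pytest.approx(pod_length(contour, scale), rel=0.02)
        assert arc >= chord

    def test_bend_reduces_chord_to_arc_ratio(self):
        ratios = []
        for bend in (0.0, 30.0):
            img, _, _ = generate_pod_image(
                PodShapeSpec(length_cm=5.0, width_cm=1.0, bend_angle_deg=bend)
            )
            contour, scale = preprocess(img)
            chord, arc, _ = chord_and_arc(contour, scale)
            ratios.append(chord / arc)
        assert ratios[1] < ratios[0]

    def test_coarse_hull_raises(self, scale50):
        from podpheno.preprocessing import Contour

        square = Contour(points=np.array([[0, 0], [10, 0], [10, 10], [0, 10.0]]))
        with pytest.raises(ValueError, match="hull"):
            chord_and_arc(square, scale50)


class TestMeasure:
    def test_all_traits_within_three_percent_of_generator(self):
        spec = PodShapeSpec(length_cm=4.56, width_cm=1.02)
        img, truth, _ = generate_pod_image(spec)
        m = measure(img)
        for k, v in m.as_dict().items():
            assert v == pytest.approx(truth.as_dict()[k], rel=0.03), k

    def test_deterministic(self):
        img, _, _ = generate_pod_image(PodShapeSpec(seed=4))
        assert measure(img) == measure(img)

    def test_invariants_enforced_by_type(self):
        with pytest.raises(ValueError):
            PodPhenotype(length_cm=1.0, width_cm=2.0, area_cm2=1.0, chord_cm=1.0, arc_cm=1.5)
        with pytest.raises(ValueError):
            PodPhenotype(length_cm=5.0, width_cm=1.0, area_cm2=4.0, chord_cm=3.0, arc_cm=2.0)

    def test_rounding_matches_reporting_precision(self):
        img, _, _ = generate_pod_image(PodShapeSpec())
        m = measure(img, round_decimals=2)
        for v in m.as_dict().values():
            assert v == round(v, 2)

    def test_scale_equivariance(self):
        m1 = measure(generate_pod_image(PodShapeSpec(px_per_cm=50.0))[0])
        m2 = measure(
            generate_pod_image(
                PodShapeSpec(px_per_cm=100.0, image_size=(840, 1120))
            )[0]
        )
        for k in m1.as_dict():
            assert m2.as_dict()[k] == pytest.approx(m1.as_dict()[k], rel=0.01), k

    def test_preprocessing_failure_is_tagged(self):
        blank = np.full((100, 100), 230, dtype=np.uint8)
        with pytest.raises(RuntimeError, match="preprocessing"):
            measure(blank)
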