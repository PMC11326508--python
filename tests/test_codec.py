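import numpy as np
import pytest

from spinedet.annotations import CenterPoint, Landmark, VertebraQuad
from spinedet.label_codec import (
    CodecConfig,
    EncodedTargets,
    PolarCorner,
    adaptive_centers,
    corners_to_polar,
    decode_landmarks,
    encode_all,
    encode_avie,
    encode_center_offset,
    encode_cpie,
    encode_heatmap,
    nms,
    polar_to_cartesian,
    topk_centers,
)
from spinedet.synthetic_spine import SpineSimParams, generate_case

FIXED = CodecConfig(sigma_policy=("fixed", 3.0))


class TestHeatmap:
    def test_peak_value_is_one(self):
        hm = encode_heatmap([(101.0, 203.0)], FIXED)
        assert hm[np.floor(203 / 4).astype(int), np.floor(101 / 4).astype(int)] == 1.0
        assert hm.max() == 1.0

    def test_closed_form_falloff(self):
        hm = encode_heatmap([(200.0, 400.0)], FIXED)
        gy, gx = 100, 50
        for d in (1, 2, 3):
            assert hm[gy, gx + d] == pytest.approx(np.exp(-(d**2) / (2 * 3.0**2)))

    def test_overlapping_discs_max_merged(self):
        hm = encode_heatmap([(200.0, 400.0), (204.0, 400.0)], FIXED)
        assert hm[100, 50] == 1.0
        assert hm[100, 51] == 1.0
        single_a = encode_heatmap([(200.0, 400.0)], FIXED)
        single_b = encode_heatmap([(204.0, 400.0)], FIXED)
        assert np.allclose(hm, np.maximum(single_a, single_b))

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            encode_heatmap([(600.0, 100.0)], FIXED)

    def test_values_in_unit_interval(self, default_case, default_codec):
        hm = encode_all(default_case.annotation, default_codec).heatmap
        assert hm.min() >= 0.0 and hm.max() == 1.0


class TestCenterOffset:
    def test_fractional_remainder(self):
        off, mask = encode_center_offset([(10.0, 20.0)], FIXED)
        assert off[0, 5, 2] == pytest.approx(0.5)  # 10/4 - 2
        assert mask.sum() == 1

    def test_grid_multiple_gives_zero(self):
        off, mask = encode_center_offset([(8.0, 16.0)], FIXED)
        assert off[:, 4, 2].tolist() == [0.0, 0.0]

    def test_offsets_in_unit_range(self, default_case, default_codec):
        off, mask = encode_center_offset(
            default_case.annotation.center_array(), default_codec
        )
        vals = off[:, mask]
        assert np.all(vals >= 0.0) and np.all(vals < 1.0)


class TestPolar:
    def test_axis_cases(self):
        center = CenterPoint(100.0, 200.0)
        east = polar_to_cartesian(center, PolarCorner(5.0, 0.0))
        assert (east.x, east.y) == pytest.approx((105.0, 200.0))
        west = polar_to_cartesian(center, PolarCorner(5.0, np.pi))
        assert (west.x, west.y) == pytest.approx((95.0, 200.0))
        zero = polar_to_cartesian(center, PolarCorner(0.0, 1.3))
        assert (zero.x, zero.y) == pytest.approx((100.0, 200.0))

    def test_downward_angle_is_positive_half_pi(self):
        quad = VertebraQuad(
            1,
            (
                Landmark(9.0, 10.0),
                Landmark(11.0, 10.0),
                Landmark(9.0, 12.0),
                Landmark(11.0, 12.0),
            ),
        )
        pc = corners_to_polar(quad, CenterPoint(10.0, 10.0))
        # corner 3 sits at center + (-1, +2): angle in (pi/2, pi)
        below = corners_to_polar(quad, CenterPoint(10.0, 11.0))[2]
        assert below.r == pytest.approx(np.hypot(1, 1))
        east = corners_to_polar(quad, CenterPoint(9.0, 10.0))[1]
        assert east.theta == pytest.approx(0.0)
        down = PolarCorner(1.0, np.pi / 2)
        lm = polar_to_cartesian(CenterPoint(0.0, 0.0), down)
        assert (lm.x, lm.y) == pytest.approx((0.0, 1.0), abs=1e-12)

    def test_round_trip_random_quads(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = rng.uniform(50, 400, size=2)
            pts = c + rng.uniform(-30, 30, size=(4, 2))
            quad = VertebraQuad(1, tuple(Landmark(*p) for p in pts))
            center = CenterPoint(*c)
            back = [
                polar_to_cartesian(center, pc)
                for pc in corners_to_polar(quad, center)
            ]
            back_arr = np.array([[p.x, p.y] for p in back])
            assert np.abs(back_arr - pts).max() <= 1e-9


class TestIntervals:
    def test_cpie_uniform_spacing(self):
        centers = [(256.0, 100.0 + 50 * i) for i in range(17)]
        cpie, mask = encode_cpie(centers, FIXED)
        assert mask.sum() == 16
        vals = cpie[:, mask].T
        assert np.allclose(vals, [0.0, 50.0])

    def test_cpie_telescoping(self, default_case, default_codec):
        centers = default_case.annotation.center_array()
        cpie, mask = encode_cpie(centers, default_codec)
        total = cpie[:, mask].sum(axis=1)
        assert np.allclose(centers[0] + total, centers[16], atol=1e-9)

    def test_avie_abutting_rectangles_zero(self):
        corners = np.zeros((2, 4, 2))
        corners[0] = [[10, 10], [30, 10], [10, 30], [30, 30]]
        corners[1] = [[10, 30], [30, 30], [10, 50], [30, 50]]
        from spinedet.annotations import SpineAnnotation

        ann = SpineAnnotation.from_corner_array(corners, 1024, 512)
        avie, mask = encode_avie(ann, FIXED)
        assert mask.sum() == 1
        assert np.allclose(avie[:, mask], 0.0)

    def test_avie_translated_gap(self):
        corners = np.zeros((2, 4, 2))
        corners[0] = [[10, 10], [30, 10], [10, 30], [30, 30]]
        corners[1] = np.asarray([[10, 30], [30, 30], [10, 50], [30, 50]]) + [3, 7]
        from spinedet.annotations import SpineAnnotation

        ann = SpineAnnotation.from_corner_array(corners, 1024, 512)
        avie, mask = encode_avie(ann, FIXED)
        assert np.allclose(avie[:, mask].ravel(), [3, 7, 3, 7])

    def test_avie_supervises_sixteen(self, default_case, default_codec):
        _, mask = encode_avie(default_case.annotation, default_codec)
        assert mask.sum() == 16


class TestNms:
    def test_isolated_peak_unchanged(self):
        hm = np.zeros((9, 9))
        hm[4, 4] = 0.7
        assert np.array_equal(nms(hm), hm)

    def test_adjacent_smaller_suppressed(self):
        hm = np.zeros((5, 5))
        hm[2, 2], hm[2, 3] = 0.9, 0.8
        out = nms(hm)
        assert out[2, 2] == 0.9 and out[2, 3] == 0.0

    def test_plateau_all_retained_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        hm = rng.choice([0.2, 0.5, 0.5, 0.9], size=(12, 10))
        out = nms(hm)
        padded = np.pad(hm, 1, constant_values=-np.inf)
        for y in range(12):
            for x in range(10):
                window_max = padded[y : y + 3, x : x + 3].max()
                expected = hm[y, x] if hm[y, x] == window_max else 0.0
                assert out[y, x] == expected


class TestDecoding:
    def test_topk_roundtrip_and_order(self, default_case, default_codec):
        ann = default_case.annotation
        t = encode_all(ann, default_codec)
        centers = topk_centers(t.heatmap, t.center_offset, default_codec)
        assert centers.shape == (17, 2)
        assert np.all(np.diff(centers[:, 1]) > 0)
        assert np.abs(centers - ann.center_array()).max() <= 1e-6

    def test_topk_insufficient_peaks(self, default_codec):
        hm = np.zeros((256, 128))
        hm[10, 10] = 1.0
        with pytest.raises(ValueError, match="1"):
            topk_centers(hm, np.zeros((2, 256, 128)), default_codec)

    def test_adaptive_counts_extra_peaks(self, default_case, default_codec):
        t = encode_all(default_case.annotation, default_codec)
        hm = t.heatmap.copy()
        for i, x in enumerate((5, 10, 120)):
            hm[5 + 5 * i, x] = 0.06  # spurious low-confidence peaks far from the spine
        centers = adaptive_centers(hm, t.center_offset, default_codec)
        assert centers.shape[0] == 20

    def test_adaptive_threshold_strict(self, default_case, default_codec):
        t = encode_all(default_case.annotation, default_codec)
        assert adaptive_centers(t.heatmap, t.center_offset, default_codec, 1.0).shape[0] == 0
        seventeen = adaptive_centers(t.heatmap, t.center_offset, default_codec, 0.05)
        fixed = topk_centers(t.heatmap, t.center_offset, default_codec)
        assert np.allclose(np.sort(seventeen, axis=0), np.sort(fixed, axis=0))

    def test_decode_landmark_cardinality(self, default_case, default_codec):
        t = encode_all(default_case.annotation, default_codec)
        centers = topk_centers(t.heatmap, t.center_offset, default_codec)
        lm = decode_landmarks(centers, t.corner_polar, default_codec)
        assert lm.shape == (17, 4, 2)

    def test_zero_radius_collapses_to_centers(self, default_case, default_codec):
        t = encode_all(default_case.annotation, default_codec)
        centers = topk_centers(t.heatmap, t.center_offset, default_codec)
        polar = t.corner_polar.copy()
        polar[0:4] = 0.0
        lm = decode_landmarks(centers, polar, default_codec)
        assert np.allclose(lm, centers[:, None, :])

    def test_full_round_trip_random_spines(self, default_codec):
        for seed in range(20):
            ann = generate_case(SpineSimParams(seed=seed), render=False).annotation
            t = encode_all(ann, default_codec)
            centers = topk_centers(t.heatmap, t.center_offset, default_codec)
            lm = decode_landmarks(centers, t.corner_polar, default_codec)
            assert np.abs(lm - ann.corner_array()).max() <= 1e-6


def test_encode_deterministic_and_serializable(tmp_path, default_case, default_codec):
    a = encode_all(default_case.annotation, default_codec)
    b = encode_all(default_case.annotation, default_codec)
    assert np.array_equal(a.heatmap, b.heatmap)
    assert np.array_equal(a.corner_polar, b.corner_polar)
    a.save_npz(tmp_path / "t.npz")
    back = EncodedTargets.load_npz(tmp_path / "t.npz")
    assert np.array_equal(back.cpie, a.cpie)
    assert np.array_equal(back.vertebral_lines.middle, a.vertebral_lines.middle)


def test_mask_cardinalities(default_case, default_codec):
    t = encode_all(default_case.annotation, default_codec)
    assert t.center_mask.sum() == 17
    assert t.cpie_mask.sum() == 16
    assert t.avie_mask.sum() == 16
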