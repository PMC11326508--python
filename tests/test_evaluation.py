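import itertools

import numpy as np
import pytest

from conftest import make_straight_annotation, make_tilted_annotation
from spinedet.evaluation import (
    CobbAngles,
    cobb_from_landmarks,
    evaluate_case,
    evaluate_dataset,
    hungarian_match,
    mde,
    self_adaptive_mde,
    smape,
)
from spinedet.label_codec import encode_all
from spinedet.synthetic_spine import SpineSimParams, generate_case


class TestCobb:
    def test_parallel_vertebrae_zero_angles(self, straight_annotation):
        angles = cobb_from_landmarks(straight_annotation.landmark_array())
        assert angles.as_array().max() == 0.0

    def test_two_tilt_spine_main_angle(self):
        tilts = [10.0] * 8 + [-10.0] * 9
        ann = make_tilted_annotation(tilts)
        angles = cobb_from_landmarks(ann.landmark_array())
        assert angles.MT == pytest.approx(20.0, abs=1e-9)

    def test_rigid_motion_invariance(self):
        # use a case with all three angles well away from 0, where the
        # arccos is well-conditioned and the maximising pair is stable
        case = generate_case(
            SpineSimParams(
                curve_amplitudes=(60.0, 25.0), curve_frequencies=(1.0, 2.0), seed=7
            ),
            render=False,
        )
        lm = case.annotation.landmark_array()
        base = cobb_from_landmarks(lm).as_array()
        assert base.min() > 2.0
        phi = np.radians(13.0)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        moved = (lm - lm.mean(0)) @ rot.T * 1.7 + np.array([300.0, -40.0])
        assert np.allclose(
            cobb_from_landmarks(moved).as_array(), base, atol=1e-9
        )

    def test_degenerate_vertebra_rejected(self, straight_annotation):
        lm = straight_annotation.landmark_array().copy().reshape(17, 4, 2)
        lm[5] = lm[5].mean(axis=0)  # all four corners collapse
        with pytest.raises(ValueError, match="degenerate"):
            cobb_from_landmarks(lm)

    def test_recovery_on_simulated_spines(self):
        for seed in range(25):
            case = generate_case(
                SpineSimParams(
                    curve_amplitudes=(60.0, 25.0),
                    curve_frequencies=(1.0, 2.0),
                    seed=seed,
                ),
                render=False,
            )
            est = cobb_from_landmarks(case.annotation.landmark_array())
            assert np.abs(est.as_array() - case.true_cobb.as_array()).max() <= 1.0


class TestMde:
    def test_exact_match_zero(self, default_case):
        lm = default_case.annotation.landmark_array()
        assert mde(lm, lm) == 0.0

    def test_single_three_four_five_displacement(self, default_case):
        gt = default_case.annotation.landmark_array()
        pred = gt.copy()
        pred[10] += [3.0, 4.0]
        assert mde(pred, gt) == pytest.approx(5.0 / 68.0)

    def test_uniform_translation(self, default_case):
        gt = default_case.annotation.landmark_array()
        assert mde(gt + [0.0, 12.5], gt) == pytest.approx(12.5)

    def test_count_mismatch(self):
        with pytest.raises(ValueError):
            mde(np.zeros((67, 2)), np.zeros((68, 2)))


class TestSmape:
    def test_identical_zero(self):
        angles = [CobbAngles(10, 30, 15)] * 4
        assert smape(angles, angles) == (0.0, 0.0, 0.0, 0.0)

    def test_doubled_prediction(self):
        gt = [CobbAngles(10.0, 30.0, 15.0)]
        pred = [CobbAngles(20.0, 60.0, 30.0)]
        overall, pt, mt, tl = smape(pred, gt)
        assert overall == pytest.approx(100.0 / 3.0)
        assert (pt, mt, tl) == pytest.approx((100.0 / 3.0,) * 3)

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        gt = [CobbAngles(*rng.uniform(5, 40, 3)) for _ in range(6)]
        pred = [CobbAngles(*rng.uniform(5, 40, 3)) for _ in range(6)]
        assert smape(pred, gt) == pytest.approx(smape(gt, pred))

    def test_zero_denominator_named(self):
        with pytest.raises(ValueError, match="case 0"):
            smape([CobbAngles(0, 0, 0)], [CobbAngles(0, 0, 0)])


class TestHungarian:
    def test_permuted_centers_zero_cost(self, default_case):
        gt = default_case.annotation.center_array()
        rng = np.random.default_rng(0)
        perm = rng.permutation(17)
        match = hungarian_match(gt[perm], gt)
        assert match.total_cost == pytest.approx(0.0, abs=1e-12)
        assert sorted(match.pairs) == [(i, int(perm[i])) for i in range(17)]

    def test_matches_bruteforce_small_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(2, 8))
            pred = rng.uniform(0, 100, size=(n, 2))
            gt = rng.uniform(0, 100, size=(n, 2))
            cost = np.linalg.norm(pred[:, None] - gt[None], axis=2)
            brute = min(
                sum(cost[i, p[i]] for i in range(n))
                for p in itertools.permutations(range(n))
            )
            assert hungarian_match(pred, gt).total_cost == pytest.approx(brute)

    def test_rectangular_extra_predictions(self, default_case):
        gt = default_case.annotation.center_array()
        pred = np.vstack([gt, [[5.0, 5.0], [500.0, 1000.0]]])
        match = hungarian_match(pred, gt)
        assert len(match.pairs) == 17
        assert len(match.unmatched_pred) == 2

    def test_empty_prediction_rejected(self, default_case):
        with pytest.raises(ValueError, match="empty"):
            hungarian_match(np.empty((0, 2)), default_case.annotation.center_array())


class TestSelfAdaptiveMde:
    def test_self_encoding_is_zero(self, default_case, default_codec):
        t = encode_all(default_case.annotation, default_codec)
        value = self_adaptive_mde(
            t.heatmap, t.center_offset, t.corner_polar, default_case.annotation, default_codec
        )
        assert value <= 1e-6

    def test_spurious_peaks_discarded(self, default_case, default_codec):
        t = encode_all(default_case.annotation, default_codec)
        clean = self_adaptive_mde(
            t.heatmap, t.center_offset, t.corner_polar, default_case.annotation, default_codec
        )
        hm = t.heatmap.copy()
        for i, x in enumerate((5, 10, 120)):
            hm[5 + 5 * i, x] = 0.06
        noisy = self_adaptive_mde(
            hm, t.center_offset, t.corner_polar, default_case.annotation, default_codec
        )
        assert noisy == pytest.approx(clean, abs=1e-9)

    def test_matching_fixes_misordering(self, default_case):
        """A vertebra swap inflates plain MDE but not the matched error."""
        gt = default_case.annotation.corner_array()
        swapped = gt.copy()
        swapped[[4, 5]] = swapped[[5, 4]]
        assert mde(swapped, gt) > 1.0
        centers_gt = gt.mean(axis=1)
        match = hungarian_match(swapped.mean(axis=1), centers_gt)
        pred_sel = np.concatenate([swapped[r] for r, _ in match.pairs])
        gt_sel = np.concatenate([gt[c] for _, c in match.pairs])
        assert mde(pred_sel, gt_sel) == pytest.approx(0.0, abs=1e-12)


class TestReports:
    def test_identical_dataset_all_zero(self, default_case):
        lm = default_case.annotation.landmark_array()
        report = evaluate_dataset([(lm, lm), (lm, lm)])
        assert report.mde == 0.0 and report.smape == 0.0

    def test_region_split_upper_ten(self, default_case):
        gt = default_case.annotation.corner_array()
        pred = gt.copy()
        pred[:10] += [0.0, 2.0]   # displace only the upper region
        report = evaluate_case(pred, gt)
        assert report.mde_upper == pytest.approx(2.0)
        assert report.mde_lower == 0.0
        assert report.mde == pytest.approx(2.0 * 40 / 68)

    def test_pooled_mde_equals_concatenation(self):
        rng = np.random.default_rng(9)
        anns = [
            generate_case(SpineSimParams(seed=s), render=False).annotation
            for s in (1, 2)
        ]
        preds = [a.landmark_array() + rng.normal(size=(68, 2)) for a in anns]
        gts = [a.landmark_array() for a in anns]
        report = evaluate_dataset(list(zip(preds, gts)))
        assert report.mde == pytest.approx(
            mde(np.concatenate(preds), np.concatenate(gts))
        )
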