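"""Semantic scores, precision-recall sweeps, mCov, naive baseline."""

import networkx as nx
import numpy as np
import pytest

from tomotrace.core import PointCloud
from tomotrace.cut import InstanceSegmentation
from tomotrace.metrics import (mcov, naive_distance_grouping, pr_curve_ap_p90,
                               semantic_scores)


class TestSemanticScores:
    def test_perfect_prediction_scores_one(self, rng):
        gt = (rng.random((16, 16)) > 0.5).astype(float)
        p, r, f1 = semantic_scores(gt, gt, 0.5)
        assert (p, r, f1) == (1.0, 1.0, 1.0)

    def test_all_background_prediction_has_zero_recall_and_f1(self):
        gt = np.ones((4, 4))
        p, r, f1 = semantic_scores(np.zeros((4, 4)), gt, 0.5)
        assert r == 0.0 and f1 == 0.0

    def test_hand_constructed_confusion_matrix(self):
        # TP=6, FP=2, FN=2 -> P = R = F1 = 0.75
        gt = np.zeros(16)
        gt[:8] = 1
        pred = np.zeros(16)
        pred[:6] = 0.9       # 6 TP
        pred[8:10] = 0.9     # 2 FP
        p, r, f1 = semantic_scores(pred.reshape(4, 4), gt.reshape(4, 4), 0.5)
        assert (p, r, f1) == (0.75, 0.75, 0.75)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            semantic_scores(np.zeros((2, 2)), np.zeros((3, 3)))


class TestPRCurve:
    def test_perfectly_ranked_probabilities_give_ap_one(self):
        pred = np.array([0.9, 0.8, 0.2, 0.1])
        gt = np.array([1, 1, 0, 0])
        _, ap, p90 = pr_curve_ap_p90(pred, gt)
        assert ap == pytest.approx(1.0)
        assert p90 == pytest.approx(1.0)

    def test_hand_swept_three_threshold_case(self):
        # ranking [fg, bg, fg]: AP = 0.5*1 + 0.5*(2/3) = 5/6
        pred = np.array([0.9, 0.8, 0.7])
        gt = np.array([1, 0, 1])
        _, ap, p90 = pr_curve_ap_p90(pred, gt)
        assert ap == pytest.approx(5.0 / 6.0)
        assert p90 == pytest.approx(2.0 / 3.0)

    def test_sweep_bottom_threshold_reaches_full_recall(self):
        # at the lowest distinct threshold every pixel is positive, so the
        # sweep always contains the recall-1 operating point and P90 falls
        # back to its precision when nothing better exists
        pred = np.concatenate([np.full(8, 0.9), np.full(2, 0.0), np.full(4, 0.5)])
        gt = np.concatenate([np.ones(10), np.zeros(4)])
        curve, ap, p90 = pr_curve_ap_p90(pred, gt)
        assert curve.recall[-1] == 1.0
        assert p90 == pytest.approx(10.0 / 14.0)

    def test_empty_ground_truth_is_an_error(self):
        with pytest.raises(ValueError):
            pr_curve_ap_p90(np.ones(4), np.zeros(4))

    def test_recall_non_increasing_in_threshold(self, rng):
        pred = rng.random(200)
        gt = (rng.random(200) > 0.7).astype(float)
        curve, _, _ = pr_curve_ap_p90(pred, gt)
        # thresholds descend, so recall must be non-decreasing along the sweep
        assert np.all(np.diff(curve.recall) >= 0)


class TestMCov:
    def test_identical_segmentations_score_one(self, chain_cloud):
        seg = InstanceSegmentation(chain_cloud.labels)
        assert mcov(chain_cloud, seg, chain_cloud, seg) == 1.0

    def test_two_equal_chains_merged_scores_half(self):
        coords = np.column_stack([np.arange(10, dtype=float), np.zeros(10)])
        cloud = PointCloud(coords)
        gt = InstanceSegmentation(np.array([0] * 5 + [1] * 5))
        pred = InstanceSegmentation(np.zeros(10, int))
        assert mcov(cloud, gt, cloud, pred) == pytest.approx(0.5)

    def test_empty_prediction_scores_zero(self):
        coords = np.column_stack([np.arange(4, dtype=float), np.zeros(4)])
        cloud = PointCloud(coords)
        gt = InstanceSegmentation(np.array([0, 0, 1, 1]))
        far = PointCloud(coords + 1e6)
        pred = InstanceSegmentation(np.zeros(4, int))
        assert mcov(cloud, gt, far, pred, match_radius=1.0) == 0.0

    def test_invariant_under_relabeling_both_sides(self, noisy_chain_cloud, rng):
        labels = noisy_chain_cloud.labels
        seg = InstanceSegmentation(labels)
        remap = {lab: i for i, lab in enumerate(rng.permutation(np.unique(labels[labels >= 0])))}
        relabeled = np.array([remap.get(l, -1) for l in labels])
        score_a = mcov(noisy_chain_cloud, seg, noisy_chain_cloud,
                       InstanceSegmentation(np.where(relabeled >= 0, relabeled, 999)))
        assert score_a == pytest.approx(1.0)

    def test_noise_points_excluded_from_ground_truth(self):
        coords = np.column_stack([np.arange(6, dtype=float), np.zeros(6)])
        cloud = PointCloud(coords)
        gt = InstanceSegmentation(np.array([0, 0, 0, -1, -1, 1]))
        pred = InstanceSegmentation(np.array([0, 0, 0, 1, 1, 2]))
        # both real instances perfectly recovered; clutter ignored
        assert mcov(cloud, gt, cloud, pred) == 1.0

    def test_no_instances_is_an_error(self):
        cloud = PointCloud(np.zeros((2, 2)))
        seg = InstanceSegmentation(np.array([-1, -1]))
        with pytest.raises(ValueError):
            mcov(cloud, seg, cloud, seg)


class TestNaiveDistanceGrouping:
    def test_collinear_unit_spaced_points_form_one_instance(self):
        cloud = PointCloud(np.column_stack([np.arange(10, dtype=float), np.zeros(10)]))
        seg = naive_distance_grouping(cloud)
        assert seg.n_instances == 1

    def test_well_separated_clusters_stay_apart(self):
        a = np.column_stack([np.arange(5, dtype=float), np.zeros(5)])
        b = a + [500.0, 0.0]
        seg = naive_distance_grouping(PointCloud(np.vstack([a, b])))
        assert seg.n_instances == 2

    def test_plus_sign_capped_variant_splits_arms(self):
        # centre 0, arms east (1,2), west (3,4), north (5,6), south (7,8)
        coords = np.array([[0, 0], [1, 0], [2, 0], [-1, 0], [-2, 0],
                           [0, 1], [0, 2], [0, -1], [0, -2]], dtype=float)
        cloud = PointCloud(coords)
        unlimited = naive_distance_grouping(cloud, max_neighbors=None)
        capped = naive_distance_grouping(cloud, max_neighbors=2)
        assert unlimited.n_instances == 1
        # greedy by ascending (distance, i, j): centre accepts (0,1), (0,3)
        # then is saturated; north and south arms detach
        sets = {frozenset(np.flatnonzero(capped.labels == lab).tolist())
                for lab in np.unique(capped.labels)}
        assert sets == {frozenset({0, 1, 2, 3, 4}), frozenset({5, 6}),
                        frozenset({7, 8})}

    def test_unlimited_variant_matches_components_oracle(self, rng):
        for _ in range(10):
            cloud = PointCloud(rng.random((30, 2)) * 10)
            seg = naive_distance_grouping(cloud, max_neighbors=None)
            from scipy.spatial.distance import cdist
            d = cdist(cloud.coords, cloud.coords)
            np.fill_diagonal(d, np.inf)
            t = d.min(axis=1).mean()
            g = nx.Graph()
            g.add_nodes_from(range(30))
            ii, jj = np.nonzero(np.triu(d <= t, 1))
            g.add_edges_from(zip(ii.tolist(), jj.tolist()))
            ours = {frozenset(np.flatnonzero(seg.labels == lab).tolist())
                    for lab in np.unique(seg.labels)}
            assert ours == {frozenset(c) for c in nx.connected_components(g)}

    def test_single_point_is_one_instance(self):
        seg = naive_distance_grouping(PointCloud([[0.0, 0.0]]))
        assert seg.n_instances == 1
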