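"""Edge transformer: representation, prediction contracts, training loop."""

import numpy as np
import pytest

from tomotrace.core import EdgeMatrix, PointCloud, chain_ground_truth
from tomotrace.dist import (DistModel, DistModelConfig, TrainConfig,
                            build_pair_representation, load_checkpoint,
                            predict_edges, predict_edges_chunked,
                            save_checkpoint, train_dist, validation_loss)
from tomotrace.simulate import SimSpec, simulate_filaments

from conftest import rigid_motion

TINY = DistModelConfig(n_layers=2, node_dim=8, edge_dim=8, n_heads=2,
                       hidden_dim=16, max_points=500, seed=0)


def tiny_chain_data(n, seed=0):
    data = []
    for i in range(n):
        spec = SimSpec(n_instances=2, points_per_instance=(6, 10),
                       jiggle_amplitude=0.5, noise_fraction=0.0,
                       drop_fraction=0.0, seed=seed * 1000 + i)
        cloud = simulate_filaments(spec)
        data.append((cloud, chain_ground_truth(cloud)))
    return data


class TestPairRepresentation:
    def test_rigid_motion_leaves_edge_features_unchanged(self, rng):
        coords = rng.uniform(0, 50, size=(12, 3))
        cfg = DistModelConfig(scale_s=5.0)
        _, ref = build_pair_representation(PointCloud(coords), cfg)
        _, moved = build_pair_representation(
            PointCloud(rigid_motion(coords, rng)), cfg)
        np.testing.assert_allclose(moved, ref, atol=1e-9)

    def test_single_point_cloud(self):
        _, feats = build_pair_representation(PointCloud([[0.0, 0.0]]), TINY)
        assert feats.shape == (1, 1, TINY.n_rbf)

    def test_features_match_per_pair_basis_evaluation(self, rng):
        coords = rng.uniform(0, 10, size=(5, 2))
        cfg = DistModelConfig(scale_s=3.0, n_rbf=16)
        _, feats = build_pair_representation(PointCloud(coords), cfg)
        centers = np.linspace(0, 1, 16)
        sigma = 1.0 / 15
        for i in range(5):
            for j in range(5):
                if i == j:
                    w = 0.0
                else:
                    d2 = np.sum((coords[i] - coords[j]) ** 2)
                    w = np.exp(-d2 / (2 * 9.0))
                expected = np.exp(-((w - centers) ** 2) / (2 * sigma ** 2))
                np.testing.assert_allclose(feats[i, j], expected, atol=1e-12)

    def test_oversized_cloud_must_go_through_chunking(self, rng):
        cloud = PointCloud(rng.random((30, 2)))
        cfg = DistModelConfig(max_points=20)
        with pytest.raises(ValueError):
            build_pair_representation(cloud, cfg)


class TestPredictEdges:
    def test_untrained_model_output_in_open_unit_interval_and_symmetric(self, rng):
        model = DistModel(TINY)
        probs = predict_edges(model, PointCloud(rng.uniform(0, 30, (15, 2))))
        off = probs.values[~np.eye(15, dtype=bool)]
        assert np.all((off > 0) & (off < 1))
        np.testing.assert_allclose(probs.values, probs.values.T, atol=1e-6)
        assert np.all(np.diagonal(probs.values) == 0)

    def test_permutation_equivariance(self, rng):
        model = DistModel(TINY)
        coords = rng.uniform(0, 30, (10, 2))
        ref = predict_edges(model, PointCloud(coords)).values
        perm = rng.permutation(10)
        got = predict_edges(model, PointCloud(coords[perm])).values
        np.testing.assert_allclose(got, ref[np.ix_(perm, perm)], atol=1e-9)

    def test_rigid_motion_invariance(self, rng):
        model = DistModel(TINY)
        coords = rng.uniform(0, 30, (10, 3))
        ref = predict_edges(model, PointCloud(coords)).values
        for _ in range(5):
            got = predict_edges(model, PointCloud(rigid_motion(coords, rng))).values
            np.testing.assert_allclose(got, ref, atol=1e-5)


class TestChunkedPrediction:
    def test_small_cloud_identical_to_direct_prediction(self, rng):
        model = DistModel(TINY)
        cloud = PointCloud(rng.uniform(0, 30, (12, 2)))
        np.testing.assert_array_equal(predict_edges_chunked(model, cloud).values,
                                      predict_edges(model, cloud).values)

    def test_separated_chains_in_different_chunks_have_zero_cross_probs(self):
        cfg = DistModelConfig(n_layers=2, node_dim=8, edge_dim=8, n_heads=2,
                              hidden_dim=16, max_points=10, seed=0)
        model = DistModel(cfg)
        a = np.column_stack([np.linspace(0, 9, 10), np.zeros(10)])
        b = np.column_stack([np.linspace(1000, 1009, 10), np.zeros(10)])
        cloud = PointCloud(np.vstack([a, b]))
        probs = predict_edges_chunked(model, cloud)
        assert probs.values[:10, 10:].max() == 0.0

    def test_straddling_chain_consecutive_pairs_covered_by_overlap(self):
        cfg = DistModelConfig(n_layers=2, node_dim=8, edge_dim=8, n_heads=2,
                              hidden_dim=16, max_points=10, seed=0)
        model = DistModel(cfg)
        coords = np.column_stack([np.linspace(0, 29, 30), np.zeros(30)])
        probs = predict_edges_chunked(model, PointCloud(coords))
        consecutive = np.diagonal(probs.values, offset=1)
        assert np.all(consecutive > 0)


class TestTraining:
    def test_validation_loss_decreases_on_small_corpus(self):
        data = tiny_chain_data(12, seed=1)
        model, history = train_dist(
            data[:10], data[10:], TINY,
            TrainConfig(learning_rate=2e-3, patience_epochs=50, max_epochs=5, seed=0))
        assert history["val_loss"][-1] < history["val_loss"][0]
        assert all(np.isfinite(v) for v in history["train_loss"])

    def test_constant_validation_loss_stops_after_patience_epochs(self):
        data = tiny_chain_data(3, seed=2)
        model, history = train_dist(
            data, [], TINY,
            TrainConfig(learning_rate=1e-3, patience_epochs=5, max_epochs=100, seed=0),
            val_evaluator=lambda m: 1.0)
        assert history["epoch"][-1] == 6

    def test_identical_seeds_give_identical_histories(self):
        data = tiny_chain_data(4, seed=3)
        cfg = TrainConfig(learning_rate=1e-3, patience_epochs=10, max_epochs=3, seed=7)
        _, h1 = train_dist(data[:3], data[3:], TINY, cfg)
        _, h2 = train_dist(data[:3], data[3:], TINY, cfg)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_dist([], [], TINY, TrainConfig(learning_rate=1e-3))

    def test_prediction_invariants_hold_after_training(self, rng):
        data = tiny_chain_data(4, seed=4)
        model, _ = train_dist(data[:3], data[3:], TINY,
                              TrainConfig(learning_rate=2e-3, patience_epochs=10,
                                          max_epochs=2, seed=0))
        probs = predict_edges(model, data[0][0])
        probs.check(atol=1e-6)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, rng, tmp_path):
        model = DistModel(TINY)
        cloud = PointCloud(rng.uniform(0, 30, (8, 2)))
        ref = predict_edges(model, cloud).values
        path = tmp_path / "dist.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        np.testing.assert_array_equal(predict_edges(loaded, cloud).values, ref)
        assert loaded.config == model.config
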