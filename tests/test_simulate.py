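"""Synthetic point clouds, augmentation, rasterization and data splits."""

import numpy as np
import pytest

from tomotrace.core import chain_ground_truth, surface_ground_truth
from tomotrace.morpho import fit_sphere
from tomotrace.simulate import (SimSpec, augment_cloud, make_split,
                                rasterize_filaments, simulate_filaments,
                                simulate_surfaces, synthetic_tube_image)


class TestFilamentGenerator:
    def test_seeded_runs_are_identical(self):
        spec = SimSpec(seed=42)
        a = simulate_filaments(spec)
        b = simulate_filaments(spec)
        np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_counts_and_arclength_spacing(self):
        spec = SimSpec(n_instances=5, points_per_instance=(40, 40), spacing=10.0,
                       jiggle_amplitude=0.0, noise_fraction=0.0, drop_fraction=0.0,
                       seed=3)
        cloud = simulate_filaments(spec)
        assert cloud.n_points == 200
        assert len(np.unique(cloud.labels)) == 5
        for inst in cloud.instance_ids():
            idx = np.flatnonzero(cloud.labels == inst)
            seq = idx[np.argsort(cloud.order[idx])]
            steps = np.linalg.norm(np.diff(cloud.coords[seq], axis=0), axis=1)
            np.testing.assert_allclose(steps, 10.0, rtol=0.10)

    def test_zero_instances_gives_empty_cloud(self):
        assert simulate_filaments(SimSpec(n_instances=0)).n_points == 0

    def test_ground_truth_degree_bound_holds(self):
        for seed in range(5):
            spec = SimSpec(seed=seed)
            cloud = augment_cloud(simulate_filaments(spec), spec)
            gt = chain_ground_truth(cloud)
            assert gt.values.sum(axis=0).max() <= 2


class TestSurfaceGenerator:
    def test_unperturbed_sphere_round_trips_through_sphere_fit(self):
        spec = SimSpec(geometry="surface", dims=3, n_instances=1,
                       radius_range=(25.0, 25.0), seed=5)
        shell = simulate_surfaces(spec, perturb=0.0, axis_jitter=0.0)
        fit = fit_sphere(shell.coords)
        assert fit.radius == pytest.approx(25.0, rel=0.01)

    def test_distant_instances_have_no_cross_edges(self):
        spec = SimSpec(geometry="surface", dims=3, n_instances=2,
                       radius_range=(20.0, 20.0), seed=8)
        cloud = simulate_surfaces(spec)
        # push the two shells ten radii apart
        cloud.coords[cloud.labels == 1] += 400.0
        gt = surface_ground_truth(cloud, k=8)
        a = cloud.labels == 0
        assert gt.values[np.ix_(a, ~a)].sum() == 0

    def test_seeded_reproducibility(self):
        spec = SimSpec(geometry="surface", dims=3, seed=9)
        np.testing.assert_array_equal(simulate_surfaces(spec).coords,
                                      simulate_surfaces(spec).coords)


class TestAugmentation:
    def test_all_zero_spec_is_identity(self, chain_cloud):
        spec = SimSpec(jiggle_amplitude=0.0, noise_fraction=0.0, drop_fraction=0.0)
        out = augment_cloud(chain_cloud, spec)
        np.testing.assert_array_equal(out.coords, chain_cloud.coords)

    def test_noise_count_follows_floor_rule(self):
        spec = SimSpec(n_instances=5, points_per_instance=(40, 40),
                       jiggle_amplitude=0.0, noise_fraction=0.1, drop_fraction=0.0,
                       seed=3)
        cloud = simulate_filaments(spec)
        out = augment_cloud(cloud, spec)
        assert (out.labels == -1).sum() == 20       # floor(0.1 * 200)
        assert out.n_points == 220

    def test_jiggle_displacement_bounded_by_amplitude(self, chain_cloud):
        spec = SimSpec(jiggle_amplitude=3.0, noise_fraction=0.0, drop_fraction=0.0)
        out = augment_cloud(chain_cloud, spec)
        disp = np.linalg.norm(out.coords - chain_cloud.coords, axis=1)
        assert disp.max() <= 3.0 + 1e-12

    def test_drops_recompact_order_ranks(self):
        spec = SimSpec(n_instances=2, points_per_instance=(20, 20),
                       jiggle_amplitude=0.0, noise_fraction=0.0, drop_fraction=0.2,
                       seed=11)
        cloud = simulate_filaments(spec)
        out = augment_cloud(cloud, spec)
        for inst in out.instance_ids():
            ranks = np.sort(out.order[out.labels == inst])
            np.testing.assert_array_equal(ranks, np.arange(len(ranks)))

    def test_out_of_bound_fractions_rejected(self):
        with pytest.raises(ValueError):
            SimSpec(noise_fraction=0.2)
        with pytest.raises(ValueError):
            SimSpec(drop_fraction=1.0)


class TestRasterization:
    def test_straight_tube_cross_section_width(self):
        from tomotrace.core import PointCloud
        n = 20
        coords = np.column_stack([np.linspace(20, 300, n), np.full(n, 80.0)])
        cloud = PointCloud(coords, labels=np.zeros(n, int), order=np.arange(n))
        mask = rasterize_filaments(cloud, 25.0, (32, 64), 50.0)   # 5 nm/px
        widths = mask.data[:, 20:44].sum(axis=0)
        assert np.all(np.abs(widths - 5) <= 1)

    def test_empty_cloud_gives_empty_mask(self):
        from tomotrace.core import PointCloud
        cloud = PointCloud(np.empty((0, 2)), np.empty(0, int), np.empty(0, int))
        assert rasterize_filaments(cloud, 25.0, (16, 16), 50.0).data.sum() == 0


class TestMakeSplit:
    def test_three_rules_on_ten_real_eight_sim(self):
        real = [f"r{i}" for i in range(10)]
        sim = [f"s{i}" for i in range(8)]
        train, val = make_split(real, sim, seed=0)
        assert len(val) == 2
        assert all(v.startswith("r") for v in val)
        assert len(train) == 16
        assert sum(t.startswith("s") for t in train) == 8   # sim = 50% of training
        assert set(v for v in val).isdisjoint(train)

    def test_no_sim_gives_plain_split(self):
        train, val = make_split(list(range(10)), [], seed=0)
        assert len(train) == 8 and len(val) == 2

    def test_sim_duplicated_when_scarce(self):
        train, val = make_split(list("abcdefghij"), ["S"], seed=0)
        assert train.count("S") == 8

    def test_too_few_real_clouds_is_an_error(self):
        with pytest.raises(ValueError):
            make_split(["only"], [], seed=0)

    def test_seeded_determinism(self):
        a = make_split(list(range(20)), list(range(100, 110)), seed=5)
        b = make_split(list(range(20)), list(range(100, 110)), seed=5)
        assert a == b


class TestTubeImages:
    def test_target_matches_rasterized_foreground(self):
        img, target = synthetic_tube_image(3)
        assert img.shape == target.shape == (64, 64)
        assert set(np.unique(target)).issubset({0.0, 1.0})
        assert 0.0 < target.mean() < 0.5
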