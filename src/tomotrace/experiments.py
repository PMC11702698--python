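"""Reproducible desk-scale experiments on synthetic data.

Each function here generates its own inputs from the synthetic-data module,
runs one part of the pipeline, and measures the result. They are the backbone
of the validation suite and of ``scripts/acceptance.py``; problem sizes are
chosen so every experiment runs in minutes on a single CPU (see
docs/methods.md for the rationale behind each size).
"""

from __future__ import annotations

import numpy as np

from .core import EdgeMatrix, GraphCutParams, PointCloud, chain_ground_truth
from .cut import InstanceSegmentation, chain_cut, surface_cut
from .dist import DistModel, DistModelConfig, TrainConfig, predict_edges, train_dist
from .fnet import FNetConfig, fnet_forward, train_fnet
from .mask import refine_mask, skeleton_points, voxel_downsample
from .metrics import mcov, semantic_scores
from .morpho import fit_sphere
from .simulate import (SimSpec, augment_cloud, rasterize_filaments,
                       simulate_filaments, simulate_surfaces, synthetic_tube_patches)

__all__ = [
    "make_chain_cloud", "chain_oracle_recovery", "surface_oracle_agreement",
    "train_chain_dist", "evaluate_chain_model", "train_toy_fnet",
    "pipeline_closure", "sphere_recovery",
]


def make_chain_cloud(seed: int, n_instances: int = 3,
                     points_per_instance=(10, 18)):
    """One augmented 2D filament cloud with its chain ground-truth graph."""
    spec = SimSpec(n_instances=n_instances, points_per_instance=points_per_instance,
                   seed=seed)
    cloud = augment_cloud(simulate_filaments(spec), spec)
    return cloud, chain_ground_truth(cloud)


def chain_oracle_recovery(n_clouds: int = 50, seed: int = 1):
    """Chain cut on oracle probabilities (1 on true consecutive pairs, 0
    elsewhere; noise points at 0): returns the per-cloud mCov list.

    Perfect probabilities must give perfect recovery, so every value should
    be exactly 1.0.
    """
    scores = []
    for i in range(n_clouds):
        cloud, gt = make_chain_cloud(seed * 10007 + i)
        seg = chain_cut(cloud, EdgeMatrix(gt.values.copy()), GraphCutParams())
        scores.append(mcov(cloud, InstanceSegmentation(cloud.labels), cloud, seg))
    return scores


def surface_oracle_agreement(n_matrices: int = 100, seed: int = 1,
                             max_points: int = 200) -> float:
    """Fraction of random thresholded matrices on which the surface cut
    matches an independent connected-components oracle (networkx) exactly,
    up to instance relabeling."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    matches = 0
    for _ in range(n_matrices):
        n = int(rng.integers(2, max_points + 1))
        upper = np.triu(rng.random((n, n)), 1)
        probs = upper + upper.T
        threshold = float(rng.uniform(0.3, 0.9))
        seg = surface_cut(PointCloud(rng.random((n, 2))), EdgeMatrix(probs), threshold)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        ii, jj = np.nonzero(np.triu(probs > threshold, 1))
        g.add_edges_from(zip(ii.tolist(), jj.tolist()))
        oracle_sets = {frozenset(c) for c in nx.connected_components(g)}
        ours = {frozenset(np.flatnonzero(seg.labels == lab).tolist())
                for lab in np.unique(seg.labels)}
        matches += oracle_sets == ours
    return matches / n_matrices


def train_chain_dist(seed: int, n_train: int = 200, n_layers: int = 4,
                     epochs: int = 5, learning_rate: float = 1e-3):
    """Train a small edge transformer on synthetic 2D filament clouds.

    Returns the trained model. The learning rate is raised above the
    full-scale default because the corpus is three orders of magnitude
    smaller (see docs/methods.md).
    """
    data = [make_chain_cloud(seed * 1_000_003 + i) for i in range(n_train + 5)]
    train_set, val_set = data[:n_train], data[n_train:]
    model, _ = train_dist(
        train_set, val_set,
        DistModelConfig(n_layers=n_layers, max_points=500, seed=seed),
        TrainConfig(learning_rate=learning_rate, patience_epochs=epochs,
                    max_epochs=epochs, seed=seed))
    return model


def evaluate_chain_model(model: DistModel, seed: int, n_clouds: int = 20) -> float:
    """Held-out mean mCov of predict-edges + chain-cut on fresh clouds."""
    scores = []
    for i in range(n_clouds):
        cloud, _ = make_chain_cloud(seed * 7_000_003 + 999 + i)
        seg = chain_cut(cloud, predict_edges(model, cloud), GraphCutParams())
        scores.append(mcov(cloud, InstanceSegmentation(cloud.labels), cloud, seg))
    return float(np.mean(scores))


def train_toy_fnet(seed: int, dual_decoder: bool = True, n_images: int = 24,
                   patch: int = 64, epochs: int = 25,
                   learning_rate: float = 3e-3, data_seed: int | None = None):
    """Train a 5-level FNet (base 8) on synthetic low-contrast tube patches;
    returns (model, held-out mean F1 at threshold 0.5).

    ``data_seed`` fixes the corpus independently of the training seed so
    that architecture comparisons can be paired on identical data.
    """
    train_set, val_set = synthetic_tube_patches(
        n_images, patch, seed=seed if data_seed is None else data_seed)
    config = FNetConfig(n_levels=5, base_channels=8, patch_shape=patch,
                        overlap=16, learning_rate=learning_rate,
                        patience_epochs=250, max_epochs=epochs, seed=seed,
                        dual_decoder=dual_decoder)
    model, _ = train_fnet(train_set, val_set, config)
    f1s = [semantic_scores(fnet_forward(model, img), target, 0.5)[2]
           for img, target in val_set]
    return model, float(np.mean(f1s))


def pipeline_closure(seed: int, pixel_size: float = 50.0, diameter: float = 25.0):
    """Rasterize filaments as 25 nm tubes, run the mask-to-cloud pipeline,
    and measure fidelity.

    Returns (max distance of recovered points to the generating centerline
    in pixel units, down-sampling reduction factor).
    """
    from scipy.spatial import cKDTree

    spec = SimSpec(n_instances=2, points_per_instance=(15, 25), dims=3,
                   jiggle_amplitude=0.0, noise_fraction=0.0, drop_fraction=0.0,
                   spacing=12.0, seed=seed)
    cloud = simulate_filaments(spec)
    nm_per_px = pixel_size / 10.0
    extent = int(np.ceil(cloud.coords.max() / nm_per_px)) + 10
    mask = rasterize_filaments(cloud, diameter, (extent,) * 3, pixel_size)
    refined = refine_mask(mask, 12.5)
    skeleton = skeleton_points(refined)
    dense = []
    for inst in cloud.instance_ids():
        idx = np.flatnonzero(cloud.labels == inst)
        seq = idx[np.argsort(cloud.order[idx])]
        pts = cloud.coords[seq]
        for a, b in zip(pts[:-1], pts[1:]):
            for t in np.linspace(0.0, 1.0, 50):
                dense.append(a + t * (b - a))
    dist, _ = cKDTree(np.asarray(dense)).query(skeleton.coords)
    down = voxel_downsample(skeleton)
    factor = skeleton.n_points / max(down.n_points, 1)
    return float(dist.max() / nm_per_px), float(factor)


def sphere_recovery(seed: int, radius: float = 25.0):
    """Simulate one exact spherical shell and fit it back; returns the
    absolute radius error in nm."""
    spec = SimSpec(geometry="surface", dims=3, n_instances=1,
                   radius_range=(radius, radius), seed=seed)
    shell = simulate_surfaces(spec, perturb=0.0, axis_jitter=0.0)
    fit = fit_sphere(shell.coords)
    return abs(fit.radius - radius)
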