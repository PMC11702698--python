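"""Core geometric types: point clouds, pairwise edge matrices, ground-truth graphs.

Coordinates are physical nanometres throughout. A point cloud optionally
carries per-point instance labels (``-1`` marks clutter/noise points) and,
for chain-like structures such as filaments, a per-point rank giving the
order of the point along its instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "PointCloud", "EdgeMatrix", "GraphCutParams",
    "pairwise_edge_weights", "chain_ground_truth", "surface_ground_truth",
    "median_nn_distance", "DENSE_POINT_CAP",
]

#: Largest cloud for which dense n x n edge matrices are built directly.
DENSE_POINT_CAP = 5000


@dataclass
class PointCloud:
    """A set of points in 2D or 3D (nm), optionally instance-annotated."""

    coords: np.ndarray
    labels: np.ndarray | None = None
    order: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, self.coords.shape[1] if self.coords.ndim == 2 and self.coords.shape[1] in (2, 3) else 3)
        if self.coords.shape[1] not in (2, 3):
            raise ValueError("point clouds must be 2D or 3D")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != len(self.coords):
                raise ValueError("labels length must match number of points")
        if self.order is not None:
            self.order = np.asarray(self.order, dtype=int)
            if len(self.order) != len(self.coords):
                raise ValueError("order length must match number of points")

    @property
    def n_points(self) -> int:
        return len(self.coords)

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]

    def instance_ids(self) -> np.ndarray:
        """Sorted ids of real instances (noise label -1 excluded)."""
        if self.labels is None:
            return np.empty(0, dtype=int)
        ids = np.unique(self.labels)
        return ids[ids >= 0]

    def subset(self, index: np.ndarray) -> "PointCloud":
        return PointCloud(
            self.coords[index],
            None if self.labels is None else self.labels[index],
            None if self.order is None else self.order[index],
        )


@dataclass
class EdgeMatrix:
    """Dense symmetric matrix over point pairs (weights, probabilities or 0/1)."""

    values: np.ndarray
    kind: str = "probability"

    _KINDS = ("geometric_weight", "probability", "binary")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("edge matrix must be square")
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    def check(self, atol: float = 1e-9):
        """Validate symmetry, range and zero diagonal; raise on violation."""
        v = self.values
        if v.size and not np.allclose(v, v.T, atol=atol):
            raise ValueError("edge matrix is not symmetric")
        if v.size and np.abs(np.diagonal(v)).max() > atol:
            raise ValueError("edge matrix diagonal must be zero")
        if self.kind == "binary":
            if not np.isin(v, (0.0, 1.0)).all():
                raise ValueError("binary edge matrix must contain only 0/1")
        elif v.size and (v.min() < -atol or v.max() > 1 + atol):
            raise ValueError("edge values must lie in [0, 1]")
        return self


@dataclass
class GraphCutParams:
    """Parameters shared by the graph-cut stage."""

    threshold: float = 0.5
    max_neighbors: int | None = 2   # None = unlimited (surface mode)
    scale_s: float | None = None    # nm; None = median nearest-neighbour distance

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


def median_nn_distance(cloud: PointCloud) -> float:
    """Median nearest-neighbour distance; the default kernel scale ``s``."""
    if cloud.n_points < 2:
        return 1.0
    d = cdist(cloud.coords, cloud.coords)
    np.fill_diagonal(d, np.inf)
    return float(np.median(d.min(axis=1)))


def pairwise_edge_weights(cloud: PointCloud, scale_s: float | None = None) -> EdgeMatrix:
    """Gaussian edge weights ``exp(-d_ij^2 / (2 s^2))`` over all point pairs.

    The weight depends only on pairwise Euclidean distance, so it is invariant
    to rigid motion of the cloud. The diagonal is fixed at 0 by convention.
    """
    if scale_s is None:
        scale_s = median_nn_distance(cloud)
    if scale_s <= 0:
        raise ValueError("scale_s must be positive")
    if cloud.n_points > DENSE_POINT_CAP:
        raise ValueError(
            f"cloud has {cloud.n_points} points; dense edge matrices are capped "
            f"at {DENSE_POINT_CAP} — use chunked prediction")
    d2 = cdist(cloud.coords, cloud.coords, metric="sqeuclidean")
    w = np.exp(-d2 / (2.0 * scale_s ** 2))
    np.fill_diagonal(w, 0.0)
    return EdgeMatrix(w, kind="geometric_weight")


def chain_ground_truth(cloud: PointCloud) -> EdgeMatrix:
    """Binary adjacency for chain instances: 1 iff two points are consecutive
    (order ranks differing by one) within the same instance.

    Every node therefore has degree at most two. Noise points (label -1) get
    no edges.
    """
    if cloud.labels is None:
        raise ValueError("chain ground truth requires instance labels")
    n = cloud.n_points
    adj = np.zeros((n, n))
    if n == 0:
        return EdgeMatrix(adj, kind="binary")
    if cloud.order is None:
        raise ValueError("chain ground truth requires per-point order ranks")
    for inst in cloud.instance_ids():
        idx = np.flatnonzero(cloud.labels == inst)
        ranks = cloud.order[idx]
        if np.any(ranks < 0):
            raise ValueError(f"instance {inst} has a labeled point without an order rank")
        seq = idx[np.argsort(ranks)]
        adj[seq[:-1], seq[1:]] = 1.0
        adj[seq[1:], seq[:-1]] = 1.0
    return EdgeMatrix(adj, kind="binary")


def surface_ground_truth(cloud: PointCloud, k: int = 8) -> EdgeMatrix:
    """Binary adjacency for surface instances: 1 iff one point is among the
    ``k`` nearest same-instance neighbours of the other (symmetrised by OR).

    Instances smaller than ``k + 1`` points connect to all their points.
    No cross-instance edges; noise points (label -1) get no edges.
    """
    if cloud.labels is None:
        raise ValueError("surface ground truth requires instance labels")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = cloud.n_points
    adj = np.zeros((n, n))
    for inst in cloud.instance_ids():
        idx = np.flatnonzero(cloud.labels == inst)
        m = len(idx)
        if m < 2:
            continue
        d = cdist(cloud.coords[idx], cloud.coords[idx])
        np.fill_diagonal(d, np.inf)
        kk = min(k, m - 1)
        # ties broken toward the lower point index: argsort is stable and
        # rows are in ascending original-index order already
        nn = np.argsort(d, axis=1, kind="stable")[:, :kk]
        rows = np.repeat(np.arange(m), kk)
        adj[idx[rows], idx[nn.ravel()]] = 1.0
    adj = np.maximum(adj, adj.T)
    np.fill_diagonal(adj, 0.0)
    return EdgeMatrix(adj, kind="binary")
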