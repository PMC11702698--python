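"""Greedy graph cuts: from a predicted edge-probability matrix to instances.

Chain-like structures (filaments, membranes in 2D) use the prior that every
point has at most two neighbours, so instances are grown greedily as chains
from the most confident edges. Surface-like structures (membranes in 3D)
have no such prior; instances are simply the connected components of the
thresholded probability graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import EdgeMatrix, GraphCutParams, PointCloud

__all__ = ["InstanceSegmentation", "chain_cut", "surface_cut", "merge_chunked_instances"]


@dataclass
class InstanceSegmentation:
    """A partition of a point cloud into instances.

    ``labels`` assigns every point an instance id (contiguous from 0);
    ``traversals`` holds, for chain instances, the ordered point indices of
    each instance.
    """

    labels: np.ndarray
    traversals: list = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_instances(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def filter_small(self, min_points: int) -> "InstanceSegmentation":
        """Optionally drop instances below a size; survivors are relabeled
        contiguously and dropped points get fresh singleton ids."""
        if min_points <= 1:
            return self
        ids, counts = np.unique(self.labels, return_counts=True)
        keep = set(ids[counts >= min_points])
        labels = self.labels.copy()
        remap, nxt = {}, 0
        for i, lab in enumerate(labels):
            if lab in keep:
                if lab not in remap:
                    remap[lab] = nxt
                    nxt += 1
                labels[i] = remap[lab]
        for i, lab in enumerate(self.labels):
            if lab not in keep:
                labels[i] = nxt
                nxt += 1
        traversals = [t for lab, t in enumerate(self.traversals) if lab in keep]
        return InstanceSegmentation(labels, traversals)


def _check_symmetric(probs: EdgeMatrix):
    v = probs.values
    if not np.allclose(v, v.T, atol=1e-8):
        raise ValueError("probability matrix must be symmetric")


def chain_cut(cloud: PointCloud, probs: EdgeMatrix,
              params: GraphCutParams | None = None) -> InstanceSegmentation:
    """Greedy chain growth under the at-most-two-neighbours prior.

    Repeatedly seed a new instance at the endpoint of the globally highest
    remaining edge, then extend the chain from both ends: each end attaches
    its highest-probability unassigned partner with probability >= threshold.
    A chain may close into a loop. Points left over become singletons.
    Ties break toward the lower point index.
    """
    params = params or GraphCutParams()
    _check_symmetric(probs)
    n = cloud.n_points
    if probs.n_points != n:
        raise ValueError("probability matrix size does not match cloud")
    p = probs.values.copy()
    np.fill_diagonal(p, 0.0)
    thr = params.threshold
    unassigned = np.ones(n, dtype=bool)
    traversals: list[list[int]] = []
    cand = np.where(p >= thr, p, 0.0) if thr > 0 else p.copy()

    def best_partner(node: int) -> tuple[int, float]:
        row = cand[node].copy()
        row[~unassigned] = 0.0
        j = int(np.argmax(row))          # argmax -> lowest index on ties
        return j, row[j]

    while True:
        # seed: globally highest remaining edge among unassigned pairs
        sub = cand.copy()
        sub[~unassigned, :] = 0.0
        sub[:, ~unassigned] = 0.0
        flat = int(np.argmax(sub))
        i, j = divmod(flat, n)
        if sub[i, j] < thr or sub[i, j] <= 0.0:
            break
        i, j = min(i, j), max(i, j)
        chain = [i, j]
        unassigned[i] = unassigned[j] = False
        # grow from both ends
        while True:
            head, tail = chain[0], chain[-1]
            jh, ph = best_partner(head)
            jt, pt = best_partner(tail)
            grew = False
            if ph >= thr and ph > 0 and (ph > pt or (ph == pt and jh <= jt)):
                chain.insert(0, jh)
                unassigned[jh] = False
                grew = True
            elif pt >= thr and pt > 0:
                chain.append(jt)
                unassigned[jt] = False
                grew = True
            if not grew:
                break
        traversals.append(chain)

    labels = np.full(n, -1, dtype=int)
    for lab, chain in enumerate(traversals):
        labels[chain] = lab
    nxt = len(traversals)
    for i in range(n):
        if labels[i] < 0:
            labels[i] = nxt
            traversals.append([i])
            nxt += 1
    return InstanceSegmentation(labels, traversals)


def surface_cut(cloud: PointCloud, probs: EdgeMatrix,
                threshold: float = 0.5) -> InstanceSegmentation:
    """Connected components of the graph {probability > threshold}."""
    _check_symmetric(probs)
    n = cloud.n_points
    if probs.n_points != n:
        raise ValueError("probability matrix size does not match cloud")
    adj = csr_matrix(probs.values > threshold)
    n_comp, raw = connected_components(adj, directed=False)
    # relabel so ids appear in order of first occurrence
    labels = np.empty(n, dtype=int)
    remap, nxt = {}, 0
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = nxt
            nxt += 1
        labels[i] = remap[lab]
    return InstanceSegmentation(labels)


def merge_chunked_instances(partials: list[tuple[np.ndarray, InstanceSegmentation]],
                            n_points: int) -> InstanceSegmentation:
    """Union instances from overlapping chunks that share parent points.

    ``partials`` is a list of (parent_index, segmentation) pairs where
    ``parent_index[k]`` gives the index in the parent cloud of local point k.
    Instances sharing at least one parent point merge transitively.
    """
    parent = np.arange(n_points)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for index, seg in partials:
        index = np.asarray(index, dtype=int)
        if len(index) != len(seg.labels):
            raise ValueError("parent index length does not match segmentation")
        if index.size and (index.min() < 0 or index.max() >= n_points):
            raise ValueError("parent indices out of range")
        for inst in range(seg.n_instances):
            members = index[seg.labels == inst]
            for m in members[1:]:
                union(members[0], m)

    roots = np.array([find(i) for i in range(n_points)])
    _, labels = np.unique(roots, return_inverse=True)
    # contiguous ids in order of first occurrence
    remap, nxt = {}, 0
    out = np.empty(n_points, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = nxt
            nxt += 1
        out[i] = remap[lab]
    return InstanceSegmentation(out)
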