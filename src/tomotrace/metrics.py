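"""Evaluation: pixel-wise semantic scores, precision-recall sweeps, the mean
coverage (mCov) instance metric, and the naive distance-grouping baseline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import PointCloud
from .cut import InstanceSegmentation
from .mask import VolumeImage

__all__ = [
    "PRCurve", "semantic_scores", "pr_curve_ap_p90", "mcov",
    "naive_distance_grouping",
]


@dataclass
class PRCurve:
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray


def _as_array(img) -> np.ndarray:
    return img.data if isinstance(img, VolumeImage) else np.asarray(img)


def semantic_scores(pred, gt, threshold: float = 0.5):
    """Pixel-wise precision, recall and F1 at a probability threshold.

    F1 = 2PR/(P+R); all three are 0 when undefined (no positives).
    """
    p = _as_array(pred)
    g = _as_array(gt).astype(bool)
    if p.shape != g.shape:
        raise ValueError("prediction and ground truth shapes differ")
    pos = p > threshold
    tp = int((pos & g).sum())
    fp = int((pos & ~g).sum())
    fn = int((~pos & g).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def pr_curve_ap_p90(pred, gt):
    """Precision-recall sweep over all distinct probability values.

    AP is the stepwise area sum((R_k - R_{k-1}) * P_k) over thresholds taken
    in decreasing order; P90 is the highest precision at an operating point
    with recall >= 0.90, or 0 if that recall is never reached.
    """
    p = _as_array(pred).ravel()
    g = _as_array(gt).astype(bool).ravel()
    if p.shape != g.shape:
        raise ValueError("prediction and ground truth shapes differ")
    n_pos = int(g.sum())
    if n_pos == 0:
        raise ValueError("ground truth has no foreground: recall undefined")
    thresholds = np.unique(p)[::-1]
    order = np.argsort(-p, kind="stable")
    sorted_gt = g[order]
    sorted_p = p[order]
    tp_cum = np.cumsum(sorted_gt)
    # index of the last prediction with value >= each threshold
    counts = np.searchsorted(-sorted_p, -thresholds, side="right")
    tp = tp_cum[counts - 1]
    precision = tp / counts
    recall = tp / n_pos
    dr = np.diff(np.concatenate([[0.0], recall]))
    ap = float(np.sum(dr * precision))
    reach = recall >= 0.90
    p90 = float(precision[reach].max()) if reach.any() else 0.0
    return PRCurve(thresholds, precision, recall), ap, p90


def _match_indices(gt_cloud: PointCloud, pred_cloud: PointCloud,
                   match_radius: float) -> np.ndarray:
    """Map every predicted point to a ground-truth point index (or -1)."""
    if (gt_cloud.coords.shape == pred_cloud.coords.shape
            and np.allclose(gt_cloud.coords, pred_cloud.coords)):
        return np.arange(gt_cloud.n_points)
    tree = cKDTree(gt_cloud.coords)
    dist, idx = tree.query(pred_cloud.coords)
    idx = np.asarray(idx)
    idx[np.asarray(dist) > match_radius] = -1
    return idx


def mcov(gt_cloud: PointCloud, gt_seg: InstanceSegmentation,
         pred_cloud: PointCloud, pred_seg: InstanceSegmentation,
         match_radius: float = 2.5) -> float:
    """Mean coverage: for each ground-truth instance, the best IoU achieved
    by any predicted instance, averaged over ground-truth instances.

    Ground-truth noise points (label -1 in ``gt_seg.labels``) are excluded.
    When the two clouds are not the same point set, predicted points are
    first matched to their nearest ground-truth point within
    ``match_radius`` (nm); unmatched predicted points still count in the
    union.
    """
    gt_labels = np.asarray(gt_seg.labels)
    gt_ids = np.unique(gt_labels[gt_labels >= 0])
    if gt_ids.size == 0:
        raise ValueError("ground truth has no instances")
    matched = _match_indices(gt_cloud, pred_cloud, match_radius)
    pred_labels = np.asarray(pred_seg.labels)
    pred_sets = {}
    pred_sizes = {}
    for plab in np.unique(pred_labels):
        sel = pred_labels == plab
        hits = matched[sel]
        pred_sets[plab] = set(hits[hits >= 0].tolist())
        pred_sizes[plab] = int(sel.sum())
    total = 0.0
    for gid in gt_ids:
        gt_set = set(np.flatnonzero(gt_labels == gid).tolist())
        best = 0.0
        for plab, pset in pred_sets.items():
            inter = len(gt_set & pset)
            if inter == 0:
                continue
            union = len(gt_set) + pred_sizes[plab] - inter
            best = max(best, inter / union)
        total += best
    return total / len(gt_ids)


def naive_distance_grouping(cloud: PointCloud,
                            max_neighbors: int | None = None) -> InstanceSegmentation:
    """Distance-threshold grouping baseline.

    The threshold t is the mean nearest-neighbour distance of the cloud.
    Pairs closer than t are connected — greedily by ascending distance when
    ``max_neighbors`` caps the per-node degree (the chain-like variant uses
    2; ``None`` means unlimited) — and instances are the connected
    components of the resulting graph.
    """
    n = cloud.n_points
    if n == 0:
        return InstanceSegmentation(np.empty(0, dtype=int))
    if n == 1:
        return InstanceSegmentation(np.zeros(1, dtype=int))
    from scipy.spatial.distance import cdist
    d = cdist(cloud.coords, cloud.coords)
    np.fill_diagonal(d, np.inf)
    t = float(d.min(axis=1).mean())
    ii, jj = np.nonzero(np.triu(d <= t, k=1))
    edges = sorted(zip(d[ii, jj], ii, jj))
    degree = np.zeros(n, dtype=int)
    parent = np.arange(n)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for dist, i, j in edges:
        if max_neighbors is not None and (degree[i] >= max_neighbors or degree[j] >= max_neighbors):
            continue
        degree[i] += 1
        degree[j] += 1
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    roots = np.array([find(i) for i in range(n)])
    remap, nxt = {}, 0
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in remap:
            remap[r] = nxt
            nxt += 1
        labels[i] = remap[r]
    return InstanceSegmentation(labels)
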