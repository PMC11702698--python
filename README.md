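# tomotrace

Semantic and instance segmentation of filaments and membranes in electron
micrographs and tomograms.

Large biomolecular structures — microtubules, actin, membranes, rod-shaped
viruses — appear in EM data as contiguous objects that must be separated
into *individual instances* before any quantitative analysis (filament
counts and lengths, membrane morphology, virus-vesicle contacts) is
possible. Per-pixel ("semantic") segmentation alone cannot do this:
closely packed filaments merge, and connected-component labelling of a
noisy mask over- and under-segments badly. `tomotrace` implements a
complete pipeline that goes from a raw image to labelled instances, and it
is aimed at structural and cell biologists processing tomograms or
micrographs at scale, as well as method developers who want a compact,
fully inspectable reference implementation.

## The pipeline

1. **Semantic segmentation** — a dual-decoder U-shaped CNN ("FNet"):
   one decoder with classic same-level skip connections, a second whose
   every level receives *all* encoder levels resampled to its resolution;
   their outputs are fused by a final convolution + sigmoid into a
   foreground probability map. Trained with per-pixel binary cross-entropy
   and NAdam (lr 1e-4, early stop after 250 epochs without validation
   improvement).
2. **Mask to point cloud** — the binary mask is refined by thresholding
   the Euclidean distance transform at half the expected feature size
   (12.5 nm for microtubules, 2 nm for membranes), thinned to a skeleton,
   and voxel-down-sampled by roughly a factor of ten. Coordinates leave
   this stage in physical nanometres.
3. **Edge prediction** — a geometry-invariant transformer scores every
   point pair with the probability that the two points belong to the same
   instance. Its only input is the pairwise weight matrix

   $$e_{ij} = \exp\!\left(-\,d_{ij}^2 / (2 s^2)\right),$$

   with $d_{ij}$ the Euclidean distance and $s$ a scale factor (default:
   the median nearest-neighbour distance), expanded over 16 radial basis
   functions. Because no raw coordinate enters the network, predictions
   are exactly invariant to rotations and translations — SO(n)-invariant —
   and permutation-equivariant. Training targets are ground-truth graphs:
   consecutive points along a chain (degree ≤ 2) for filaments, the 8
   nearest same-instance neighbours for membrane surfaces; the loss is
   per-pair BCE (NAdam, lr 1e-5, early stop on the moving average of
   validation loss over 100 epochs).
4. **Graph cut** — chains are grown greedily from the most confident
   edges under the at-most-two-neighbours prior; surfaces are the
   connected components of the thresholded (p > 0.5) probability graph.
5. **Quantification** — instance evaluation by mean coverage
   (mCov: mean over ground-truth instances of the best IoU achieved by any
   predicted instance), semantic evaluation by precision/recall/F1, AP and
   P90; least-squares sphere fits classify membrane vesicles (~50 nm →
   virus, larger → liposome) and report virus-liposome contacts within a
   30 nm reach.

A seeded synthetic-data module generates filament and membrane point
clouds, their ground-truth graphs, and rasterized 25 nm tube masks; every
experiment in the test suite is driven by it. The neural networks run on a
small self-contained numpy autodiff engine (`tomotrace.nn`) — no GPU or
deep-learning framework required.

## Worked example

Train a small edge transformer on 60 synthetic filament clouds (about 15 s
on one CPU core) and segment an unseen cloud:

```python
from tomotrace import (InstanceSegmentation, GraphCutParams, chain_cut,
                       mcov, naive_distance_grouping, predict_edges)
from tomotrace.experiments import make_chain_cloud, train_chain_dist

model = train_chain_dist(seed=0, n_train=60, epochs=3)

cloud, _ = make_chain_cloud(seed=424242)     # unseen: 3 filaments + clutter
gt = InstanceSegmentation(cloud.labels)
seg = chain_cut(cloud, predict_edges(model, cloud), GraphCutParams(threshold=0.5))
naive = naive_distance_grouping(cloud, max_neighbors=2)
print(f"cloud: {cloud.n_points} points, {len(cloud.instance_ids())} filaments, "
      f"{(cloud.labels == -1).sum()} noise points")
print(f"edge transformer + chain cut: {seg.n_instances} instances, "
      f"mCov = {mcov(cloud, gt, cloud, seg):.3f}")
print(f"naive distance grouping:      {naive.n_instances} instances, "
      f"mCov = {mcov(cloud, gt, cloud, naive):.3f}")
```

Output:

```
cloud: 46 points, 3 filaments, 4 noise points
edge transformer + chain cut: 7 instances, mCov = 1.000
naive distance grouping:      23 instances, mCov = 0.231
```

The cloud has 46 points: 3 filaments plus 4 clutter points. The trained
model recovers all three filaments perfectly (mCov 1.0; the extra
instances are clutter points correctly isolated as singletons), while
grouping by a distance threshold alone shatters the filaments into 23
pieces (mCov 0.23). The `tomotrace` CLI exposes the same pipeline as
subcommands (`simulate`, `mask2cloud`, `instance`, `segment`, `train-dist`,
`train-fnet`, `predict`, `score`, `vesicles`); volumes are read and written
as MRC or TIFF, point clouds as `instance_id,x,y,z` CSV (nm), and chain
instances optionally as minimal Amira SpatialGraph ASCII.

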