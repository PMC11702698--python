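# Methods

This note documents the models, the numerical choices, the synthetic data
that the tests run on, and the known limits of what those tests show.

## Edge-probability transformer

The instance-segmentation core predicts, for every pair of points in a
cloud, the probability that they belong to the same structure.

**Representation.** The network input is the Gaussian edge-weight matrix
`e_ij = exp(-d_ij^2 / (2 s^2))`. The scale `s` defaults to the median
nearest-neighbour distance of the cloud, which adapts the kernel to the
sampling density after voxel down-sampling and keeps the representation
unit-free; any fixed value (nm) can be supplied instead. Each weight is
expanded over 16 Gaussian radial basis functions with centres uniform on
[0, 1] and width 1/15 — enough resolution to distinguish "one spacing"
from "two spacings" without breaking invariance. Node features start from
a single learned vector shared by all points. Since nothing
coordinate-dependent enters except pair distances, the output is invariant
to rigid motion by construction and permutation-equivariant; the test
suite asserts both numerically.

**Blocks.** Each of the `n_layers` (default 6; 4 in the desk-scale
experiments) pre-norm blocks performs (i) multi-head attention between
nodes whose logits are biased by a linear readout of the current edge
state, (ii) a node MLP, and (iii) an edge update: the edge state is
incremented by an MLP of the two incident node features plus the previous
edge state. A linear head on the final edge state gives logits which are
symmetrised by averaging the (i,j) and (j,i) entries before the sigmoid;
the diagonal is forced to zero (self-edges carry no instance information).

**Training.** One cloud per optimisation step (clouds have unequal sizes),
NAdam, per-pair binary cross-entropy computed from logits. Positive pairs
(about n of n² entries) are up-weighted by `pos_weight = 3`; without this
the optimum under-predicts the rare "connected" class and chains fragment.
Early stopping monitors a moving average of validation loss (window
configurable, default 1) with patience 100 epochs at full scale. The
full-scale learning rate is 1e-5; the desk-scale experiments below use
1e-3, because with a corpus of 200 clouds rather than hundreds of
thousands of steps the small rate would simply never converge. Runs are
bit-reproducible for a fixed seed.

**Ground-truth graphs.** Chains: entry 1 iff two points are consecutive
(order ranks differing by 1) in the same instance; every node degree ≤ 2.
Surfaces: entry 1 iff one point is among the 8 Euclidean nearest
same-instance neighbours of the other, symmetrised by OR; instances
smaller than 9 points connect fully. Noise points (label −1) never receive
edges.

**Large clouds.** Dense n×n matrices are capped (5 000 points for the
geometric weights; `max_points` = 2 000 for inference, 500 for training).
Beyond the cap, prediction runs on overlapping spatial windows along the
longest axis — window width shrunk until every window holds at most
`max_points` points, stride half a window — and overlapping pair
probabilities merge by maximum. Spatial (not index) windows guarantee that
well-separated structures never share a chunk. Instances from chunks are
unioned transitively over shared points.

## Graph cuts

**Chains.** Greedy growth under the degree-≤2 prior: seed a new instance
at the endpoints of the globally highest remaining edge among unassigned
points; extend the chain from both ends, each end attaching its
highest-probability unassigned partner with probability ≥ threshold
(default 0.5, matching the surface rule); ties break toward the lower
point index. Leftover points become singletons; an optional `min_points`
filter can drop small instances but is off by default. A chain whose two
ends would reconnect simply stops — the partition is identical to closing
the loop, so loops are not treated specially.

**Surfaces.** Exactly the connected components of the graph
{p_ij > threshold}; the implementation delegates to scipy's sparse
connected components and the tests verify exact agreement with an
independent networkx oracle on random matrices.

## Semantic segmentation network

A U-shaped encoder (5 levels; channels `base * 2^level`; each block =
group norm → conv → LeakyReLU → conv → LeakyReLU; 2× max-pool between
levels) feeds two concurrent decoders: decoder A is a classic U with
same-level skips; decoder B at each level concatenates *all* encoder
levels resampled to that resolution (max-pool down, nearest-neighbour up)
with its upsampled previous state, fused by a 1×1 convolution. The two
decoder outputs are concatenated and reduced by a single final
convolution; a sigmoid yields probabilities. The single-decoder ablation
(decoder A only) shares the identical encoder. Up-sampling is
nearest-neighbour followed by convolution — parameter-light and free of
checkerboard artefacts. Images are standardised and rescaled to [−1, 1]
(constant images map to zero) and processed in overlapping patches
(256 px / overlap 32 at full scale; 64 px / overlap 16 in tests) that are
reassembled by central cropping, which is exact for a single-patch image.

Pixel-size normalisation before inference: tomograms resample to 15 Å/px;
micrographs finer than 10 Å/px to 4 Å/px, coarser ones to 8 Å/px
(bilinear/trilinear).

## Mask to point cloud

The distance-transform refinement keeps foreground whose EDT (in nm) is at
least half the expected feature size. Half-width is the natural threshold
for separating touching structures of a stated diameter; the exact rule is
our choice. If the threshold would erase more than 95% of the foreground —
thin membranes on coarse grids, where half the feature size is below one
pixel — the mask passes through unchanged, since an empty cloud from a
valid mask is never useful. 3D thinning reduces closed shells to medial
surfaces and tubes to medial curves; an *open* one-voxel plate can be
thinned away entirely, in which case the foreground voxels themselves are
returned. Skeleton coordinates use the voxel-centre convention
((index + ½) × spacing, x fastest) and leave the module in nm.

Voxel down-sampling replaces the points of each occupied cube by their
centroid (labels by majority vote, ties to the lower id). With no explicit
edge length, a bisection search picks the edge that reduces the point
count by a factor in [8, 12] — "about ten", stated as a goal rather than a
grid size.

## Synthetic data

The generator emulates the point clouds that the mask pipeline produces
from real data, and is the sole data source for every test.

* **Filaments** are cubic splines through 4–8 control points laid down by
  a stiff correlated random walk (direction-change scale 0.18 per step):
  biological filaments such as microtubules have persistence lengths far
  exceeding a field of view, so curves bend gently. Splines are resampled
  at uniform arc-length spacing (default 10 nm) and carry ordered labels.
  The field of view scales with instance count (constant areal density),
  and an excluded-volume rule resamples any curve that runs alongside an
  existing one closer than the 25 nm tube diameter for more than 12% of
  its points: solid tubes cannot interpenetrate, while transient crossings
  — which do occur in projections — remain allowed. Without this
  constraint the synthetic task contains parallel-hugging configurations
  that are physically impossible and undecidable from distances alone.
* **Membranes** are ellipsoidal shells (radius 20–60 nm, per-axis jitter
  ±15%) with a low-order harmonic radial perturbation (5% amplitude),
  sampled quasi-uniformly by a Fibonacci lattice at the requested spacing.
* **Augmentation** displaces every point in a uniform random direction
  with amplitude ~ U(0, 2 nm) (skeletonisation and down-sampling jitter),
  adds ⌊0.1·n⌋ clutter points labelled −1 uniformly in the bounding box
  (false positives of the semantic stage; clutter is capped at 10%), and
  drops ⌊0.05·k⌋ points per instance with order ranks re-compacted
  (missed detections). All counts follow the floor rule exactly.
* **Tube masks** sweep a 25 nm diameter tube along each chain polyline,
  rasterised via an exact Euclidean distance transform of the sampled
  centerline.
* **Tube images** for CNN training place tubes at 0.7 noise standard
  deviations below the background — low-dose contrast where a per-pixel
  threshold cannot find them.
* **Splits** follow the 80/20 train/validation rule over real-flagged
  clouds, with simulated clouds only in training, sub-sampled or
  duplicated to half of it.

What the generator does *not* model: tomographic missing-wedge anisotropy,
CTF oscillations, stain granularity, or the correlated textures of
cellular interiors. Passing tests therefore demonstrate the correctness
and learnability of the pipeline under controlled geometry and noise — not
benchmark performance on real tomograms.

## Desk-scale experiment sizes

All experiments run on one CPU core within minutes; sizes are the
package's own choices balancing statistical stability against runtime.

* **Chain-cut oracle**: 50 augmented clouds, oracle probabilities; exact
  recovery (mCov = 1.0 per cloud) is required and achieved.
* **Surface-cut oracle**: 100 random matrices (≤ 200 points) against a
  networkx connected-components oracle; exact label-set agreement.
* **Edge-model recovery**: 4 layers, node/edge width 32, 4 heads; 200
  training clouds (3 instances each of 10–18 points, full augmentation),
  5 epochs at lr 1e-3, pos_weight 3; evaluated on 20 fresh clouds. Three
  independent seeds reach held-out mCov ≥ 0.9 (typically ≈ 0.96; the
  naive distance-grouping baseline scores ≈ 0.4 on identical clouds).
* **Segmentation-CNN recovery**: 5 levels, base 8, 64² patches, 24 images
  (18 train / 6 validation), 25 epochs at lr 3e-3. The dual-decoder
  network and its single-decoder ablation train on the identical corpus
  with the same three seeds (a paired comparison, so decoder topology is
  the only varied factor); the dual decoder reaches F1 ≥ 0.8 on every
  seed and a higher 3-seed mean. At this toy scale the architectural
  margin is small (≈ 0.01–0.03 F1) and comparable to dataset-level noise,
  which is why the comparison is paired.
* **Pipeline closure**: two 3D filaments rasterised as 25 nm tubes at
  5 nm/px; every recovered point lies within 1 px of the generating
  centerline and down-sampling reduces counts by 8–12×.
* **Sphere analytics**: noiseless shells recover radius to < 1e-6 nm;
  classification uses 50 ± 10 nm (virus) and the 30 nm interaction reach,
  measured centre-to-membrane-point, because fusion sites are local
  membrane features rather than properties of the fitted sphere.

## Numerical choices and degenerate inputs

* Probabilities and weights live on [0, 1]; matrices are validated for
  symmetry (1e-9), zero diagonal and range.
* BCE is computed from logits with a stable softplus; losses are finite
  for all inputs, and seeded runs are bit-identical on one device.
* k-NN and greedy ties break toward the lower point index; `argmax`
  tie-breaks inherit numpy's first-occurrence rule, making every cut
  deterministic.
* Empty masks, empty clouds, single-point instances and constant images
  all pass through with defined results; coplanar points make the sphere
  fit raise rather than return a meaningless radius.
* The PR sweep uses thresholds at every distinct predicted value with the
  ≥ rule; at the lowest threshold every pixel is positive, so the sweep
  always contains the recall-1 operating point. P90 is the best precision
  among operating points with recall ≥ 0.9 (a defensive 0 is returned if
  no such point exists). AP is the stepwise sum Σ (R_k − R_{k−1}) P_k.

## Known limitations

* The transformer sees only pairwise distances; configurations that are
  genuinely ambiguous under rigid motion (e.g. two filaments crossing at
  grazing incidence with matching spacing) are irreducible error sources.
* The greedy chain cut is order-dependent by design and not globally
  optimal; a single confident false edge can still merge two chains.
* The numpy engine is single-threaded BLAS-bound and intended for
  desk-scale models; it trains the reference configurations in minutes but
  is not a route to the full-scale corpus.
* 3D thinning of open membrane sheets (plates with free edges) falls back
  to returning the refined foreground voxels; closed shells thin cleanly.
* `merge_chunked_instances` unions by shared points only; chunk layouts
  whose overlap misses an instance entirely cannot reconnect it.
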