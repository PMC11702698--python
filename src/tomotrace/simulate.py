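"""Seeded generators for synthetic filament and membrane point clouds.

Filaments are smooth random space curves resampled at uniform arc-length
spacing and carry ordered instance labels; membranes are harmonically
perturbed ellipsoidal shells sampled quasi-uniformly. Augmentation adds
point jiggle, uniform clutter points (label -1, at most 10% of the cloud)
and random point drops, emulating the imperfections of point clouds
extracted from real semantic masks. Filament clouds can be rasterized back
into binary tube masks (25 nm diameter by convention) to exercise the
mask-processing pipeline end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .core import PointCloud
from .mask import VolumeImage

__all__ = [
    "SimSpec", "simulate_filaments", "simulate_surfaces", "augment_cloud",
    "rasterize_filaments", "make_split", "synthetic_tube_image",
    "synthetic_tube_patches",
]


@dataclass
class SimSpec:
    """Conditions for one synthetic point-cloud draw.

    Units are nm. ``noise_fraction`` is capped at 0.10: clutter beyond ten
    percent of the cloud is not representative of a usable semantic mask.
    """

    n_instances: int = 5
    points_per_instance: tuple[int, int] = (20, 60)
    spacing: float = 10.0
    dims: int = 2
    geometry: str = "filament"
    jiggle_amplitude: float = 2.0
    noise_fraction: float = 0.1
    drop_fraction: float = 0.05
    radius_range: tuple[float, float] = (20.0, 60.0)   # surfaces only
    exclusion_diameter: float = 25.0   # filaments are solid tubes: no hugging
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.noise_fraction <= 0.1:
            raise ValueError("noise_fraction must lie in [0, 0.1]")
        if not 0.0 <= self.drop_fraction < 1.0:
            raise ValueError("drop_fraction must lie in [0, 1)")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.geometry not in ("filament", "surface"):
            raise ValueError("geometry must be 'filament' or 'surface'")


def _smooth_curve(rng: np.random.Generator, n_points: int, spacing: float,
                  dims: int, box: float) -> np.ndarray:
    """A random smooth curve resampled at uniform arc-length spacing."""
    length = (n_points - 1) * spacing
    n_ctrl = int(rng.integers(4, 9))
    # correlated random walk of control points: keeps curvature bounded
    step = length / (n_ctrl - 1)
    pts = [rng.uniform(0.2 * box, 0.8 * box, size=dims)]
    direction = rng.normal(size=dims)
    direction /= np.linalg.norm(direction)
    for _ in range(n_ctrl - 1):
        # filaments are stiff: small direction changes between control points
        turn = rng.normal(scale=0.18, size=dims)
        direction = direction + turn
        direction /= np.linalg.norm(direction)
        pts.append(pts[-1] + step * direction)
    ctrl = np.array(pts)
    t = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(ctrl, axis=0), axis=1))])
    spline = CubicSpline(t, ctrl)
    # dense arc-length table, then uniform resampling
    td = np.linspace(0.0, t[-1], 40 * n_points)
    dense = spline(td)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(n_points) * spacing
    targets = np.clip(targets, 0.0, arc[-1])
    return np.column_stack([np.interp(targets, arc, dense[:, d]) for d in range(dims)])


def simulate_filaments(spec: SimSpec) -> PointCloud:
    """Generate chain instances: ordered points along smooth random curves."""
    if spec.geometry != "filament":
        raise ValueError("spec.geometry must be 'filament'")
    rng = np.random.default_rng(spec.seed)
    # box scales with instance count so filament areal density stays constant
    box = spec.spacing * spec.points_per_instance[1] * 0.7 * max(1.0, spec.n_instances) ** (1.0 / spec.dims)
    coords, labels, order = [], [], []
    for inst in range(spec.n_instances):
        n_pts = int(rng.integers(spec.points_per_instance[0], spec.points_per_instance[1] + 1))
        # excluded volume: filaments are solid tubes, so a new curve may
        # cross existing ones (projection) but not run alongside them closer
        # than the tube diameter; resample hugging configurations
        for _ in range(25):
            curve = _smooth_curve(rng, n_pts, spec.spacing, spec.dims, box)
            if not coords:
                break
            existing = np.concatenate(coords)
            dmin = np.sqrt(((curve[:, None] - existing[None]) ** 2).sum(-1)).min(axis=1)
            if (dmin < spec.exclusion_diameter).mean() <= 0.12:
                break
        coords.append(curve)
        labels.append(np.full(n_pts, inst))
        order.append(np.arange(n_pts))
    if not coords:
        return PointCloud(np.empty((0, spec.dims)), np.empty(0, int), np.empty(0, int))
    return PointCloud(np.concatenate(coords), np.concatenate(labels), np.concatenate(order))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere sampling."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def simulate_surfaces(spec: SimSpec, perturb: float = 0.05,
                      axis_jitter: float = 0.15) -> PointCloud:
    """Generate closed shell instances: perturbed ellipsoids sampled at
    roughly ``spec.spacing`` point separation.

    ``perturb`` is the relative amplitude of the low-order harmonic radial
    deformation; ``axis_jitter`` the relative spread of the ellipsoid axes.
    Set both to 0 for exact spheres.
    """
    if spec.geometry != "surface" or spec.dims != 3:
        raise ValueError("surface simulation requires geometry='surface' and dims=3")
    rng = np.random.default_rng(spec.seed)
    box = 4.0 * spec.radius_range[1] * max(1.0, spec.n_instances ** (1 / 3))
    coords, labels = [], []
    for inst in range(spec.n_instances):
        radius = rng.uniform(*spec.radius_range)
        center = rng.uniform(0.2 * box, 0.8 * box, size=3)
        n_pts = max(8, int(round(4 * np.pi * radius ** 2 / spec.spacing ** 2)))
        unit = _fibonacci_sphere(n_pts)
        axes = radius * (1.0 + axis_jitter * rng.uniform(-1, 1, size=3))
        # low-order harmonic bump: smooth radial modulation of the shell
        if perturb > 0:
            a = rng.normal(scale=perturb, size=(3, 3))
            x, y, z = unit.T
            bump = (a[0, 0] * x + a[0, 1] * y + a[0, 2] * z
                    + a[1, 0] * x * y + a[1, 1] * y * z + a[1, 2] * z * x
                    + a[2, 0] * (x * x - y * y) + a[2, 1] * (3 * z * z - 1) / 2)
            radial = 1.0 + bump
        else:
            radial = 1.0
        shell = center + unit * axes * np.atleast_1d(radial)[:, None]
        coords.append(shell)
        labels.append(np.full(n_pts, inst))
    if not coords:
        return PointCloud(np.empty((0, 3)), np.empty(0, int))
    return PointCloud(np.concatenate(coords), np.concatenate(labels))


def augment_cloud(cloud: PointCloud, spec: SimSpec) -> PointCloud:
    """Apply jiggle, clutter and drops; counts follow the floor rule.

    Jiggle displaces every point in a uniform random direction with amplitude
    drawn from U(0, jiggle_amplitude). floor(noise_fraction * n) clutter
    points (label -1) are added uniformly in the bounding box. floor(
    drop_fraction * k) points are removed from each instance of size k, and
    chain order ranks are re-compacted.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n = cloud.n_points
    if n == 0:
        return cloud
    coords = cloud.coords.copy()
    labels = None if cloud.labels is None else cloud.labels.copy()
    order = None if cloud.order is None else cloud.order.copy()

    if spec.jiggle_amplitude > 0:
        direction = rng.normal(size=coords.shape)
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        amplitude = rng.uniform(0.0, spec.jiggle_amplitude, size=(n, 1))
        coords = coords + direction * amplitude

    n_noise = int(np.floor(spec.noise_fraction * n))
    if n_noise > 0:
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        clutter = rng.uniform(lo, hi, size=(n_noise, cloud.n_dims))
        coords = np.concatenate([coords, clutter])
        if labels is None:
            labels = np.zeros(n, dtype=int)
        labels = np.concatenate([labels, np.full(n_noise, -1)])
        if order is not None:
            order = np.concatenate([order, np.full(n_noise, -1)])

    if spec.drop_fraction > 0 and labels is not None:
        keep = np.ones(len(coords), dtype=bool)
        for inst in np.unique(labels[labels >= 0]):
            idx = np.flatnonzero(labels == inst)
            n_drop = int(np.floor(spec.drop_fraction * len(idx)))
            if n_drop > 0:
                keep[rng.choice(idx, size=n_drop, replace=False)] = False
        coords, labels = coords[keep], labels[keep]
        if order is not None:
            order = order[keep]
            # re-compact order ranks per instance
            for inst in np.unique(labels[labels >= 0]):
                idx = np.flatnonzero(labels == inst)
                order[idx] = np.argsort(np.argsort(order[idx]))
    return PointCloud(coords, labels, order)


def rasterize_filaments(cloud: PointCloud, diameter: float, image_shape: tuple,
                        pixel_size: float) -> VolumeImage:
    """Sweep a tube of the given diameter (nm) along each chain polyline and
    rasterize the union on a grid with the given pixel size (Angstrom/px).

    Uses the voxel-center convention of :func:`tomotrace.mask.skeleton_points`:
    a point at x nm maps to pixel index x / nm_per_px - 0.5.
    """
    nm_per_px = pixel_size / 10.0
    ndim = len(image_shape)
    center = np.zeros(image_shape, dtype=bool)
    if cloud.n_points and cloud.labels is not None:
        if cloud.order is None:
            raise ValueError("rasterize_filaments requires ordered chain labels")
        for inst in cloud.instance_ids():
            idx = np.flatnonzero(cloud.labels == inst)
            seq = idx[np.argsort(cloud.order[idx])]
            pts = cloud.coords[seq]
            for a, b in zip(pts[:-1], pts[1:]):
                n_sub = max(2, int(np.ceil(np.linalg.norm(b - a) / (0.25 * nm_per_px))))
                for t in np.linspace(0.0, 1.0, n_sub):
                    p = a + t * (b - a)
                    pix = np.round(p / nm_per_px - 0.5).astype(int)[::-1]  # (x,y,z)->(z,y,x)
                    if np.all(pix >= 0) and np.all(pix < np.array(image_shape)):
                        center[tuple(pix)] = True
    if not center.any():
        return VolumeImage(np.zeros(image_shape, dtype=np.uint8), pixel_size, "binary")
    dist_px = ndimage.distance_transform_edt(~center)
    mask = dist_px * nm_per_px <= diameter / 2.0
    return VolumeImage(mask.astype(np.uint8), pixel_size, "binary")


def synthetic_tube_image(seed: int, patch: int = 64, pixel_size: float = 50.0,
                         diameter: float = 25.0, snr: float = 0.7):
    """One synthetic micrograph patch: dark tubes on a noisy background.

    Returns (image, binary_target). The image mimics the low contrast of a
    dose-limited cryo micrograph: foreground is ``snr`` standard deviations
    below the noise floor (well below 1, i.e. tubes are not separable by a
    per-pixel threshold).
    """
    rng = np.random.default_rng(seed)
    nm = patch * pixel_size / 10.0
    spec = SimSpec(n_instances=int(rng.integers(1, 4)), points_per_instance=(8, 16),
                   spacing=nm / 12, dims=2, jiggle_amplitude=nm / 60,
                   noise_fraction=0.0, drop_fraction=0.0, seed=seed)
    cloud = augment_cloud(simulate_filaments(spec), spec)
    # recentre the cloud into the field of view
    span = cloud.coords.max(axis=0) - cloud.coords.min(axis=0)
    cloud.coords -= cloud.coords.min(axis=0)
    cloud.coords += rng.uniform(0, np.maximum(nm - span, 1e-6))
    mask = rasterize_filaments(cloud, diameter, (patch, patch), pixel_size)
    img = rng.normal(0.0, 1.0, size=(patch, patch)) - snr * mask.data
    return img, mask.data.astype(float)


def synthetic_tube_patches(n_images: int, patch: int = 64, seed: int = 0,
                           val_fraction: float = 0.25, snr: float = 0.7):
    """A train/validation corpus of normalised tube patches for CNN training."""
    pairs = []
    for i in range(n_images):
        img, target = synthetic_tube_image(seed * 100003 + i, patch, snr=snr)
        std = img.std()
        img = (img - img.mean()) / std
        lo, hi = img.min(), img.max()
        img = 2.0 * (img - lo) / (hi - lo) - 1.0
        pairs.append((img, target))
    n_val = max(1, int(round(val_fraction * n_images)))
    return pairs[n_val:], pairs[:n_val]


def make_split(clouds_real: list, clouds_sim: list, seed: int = 0):
    """Train/validation partition: 80/20 over real clouds, validation purely
    real, simulated clouds only in training where they are sub-sampled or
    duplicated to make up 50% of the training set.

    Returns (train, val) as lists of the input objects.
    """
    if len(clouds_real) < 2:
        raise ValueError("need at least two real clouds for a non-empty validation set")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(clouds_real))
    n_val = max(1, int(round(0.2 * len(clouds_real))))
    val = [clouds_real[i] for i in order[:n_val]]
    train_real = [clouds_real[i] for i in order[n_val:]]
    if not clouds_sim:
        return train_real, val
    n_sim = len(train_real)      # sim = 50% of training
    sim_order = rng.permutation(len(clouds_sim))
    picks = [clouds_sim[sim_order[i % len(clouds_sim)]] for i in range(n_sim)]
    train = train_real + picks
    return train, val
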