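"""Downstream quantification of segmented membranes.

Segmented vesicle instances are summarised by an algebraic least-squares
sphere fit; objects near 50 nm diameter are classified as virus particles
(mature dengue virions are ~50 nm across), larger ones as liposomes.
Virus-liposome interaction sites are membrane points within a 30 nm reach
of a virus center, the approximate span of the viral envelope proteins
during fusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import PointCloud
from .mask import VolumeImage

__all__ = [
    "SphereFit", "fit_sphere", "classify_vesicles", "interaction_sites",
    "normalize_pixel_size",
]


@dataclass
class SphereFit:
    center: np.ndarray
    radius: float
    rms_residual: float

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


def fit_sphere(points: np.ndarray | PointCloud) -> SphereFit:
    """Algebraic least-squares sphere through a 3D point set.

    Solves the linear system 2 c . p + (r^2 - |c|^2) = |p|^2 for the center
    c and radius r; exact on noiseless spherical data. Degenerate input
    (fewer than 4 points, or coplanar points) raises ValueError.
    """
    pts = points.coords if isinstance(points, PointCloud) else np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("fit_sphere expects an (n, 3) point array")
    if len(pts) < 4:
        raise ValueError("sphere fit needs at least 4 points")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts ** 2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValueError("degenerate (coplanar) points: sphere fit is ill-posed")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("degenerate points: non-positive fitted radius")
    radius = float(np.sqrt(r2))
    residual = float(np.sqrt(np.mean((np.linalg.norm(pts - center, axis=1) - radius) ** 2)))
    return SphereFit(center, radius, residual)


def classify_vesicles(fits: list[SphereFit], virus_diameter: float = 50.0,
                      band: float = 10.0) -> list[str]:
    """Label each fitted object by diameter: within ``virus_diameter +/- band``
    -> "virus"; larger -> "liposome"; smaller -> "unassigned"."""
    if band < 0:
        raise ValueError("band must be non-negative")
    labels = []
    for fit in fits:
        d = fit.diameter
        if abs(d - virus_diameter) <= band:
            labels.append("virus")
        elif d > virus_diameter + band:
            labels.append("liposome")
        else:
            labels.append("unassigned")
    return labels


def interaction_sites(virus_fits: list[SphereFit],
                      liposome_clouds: list[PointCloud | np.ndarray],
                      reach: float = 30.0) -> list[tuple]:
    """Report (virus id, liposome id, closest point, distance) for every
    virus-liposome pair with a membrane point within ``reach`` nm of the
    virus center."""
    if reach <= 0:
        raise ValueError("reach must be positive")
    pairs = []
    for vi, fit in enumerate(virus_fits):
        for li, cloud in enumerate(liposome_clouds):
            pts = cloud.coords if isinstance(cloud, PointCloud) else np.asarray(cloud, dtype=float)
            if len(pts) == 0:
                continue
            dist = np.linalg.norm(pts - fit.center, axis=1)
            k = int(np.argmin(dist))
            if dist[k] <= reach:
                pairs.append((vi, li, pts[k].copy(), float(dist[k])))
    return pairs


def normalize_pixel_size(img: VolumeImage, modality: str) -> VolumeImage:
    """Resample to the pixel size at which the semantic networks perform
    best: tomograms to 15 A/px; micrographs to 4 A/px when the input is
    finer than 10 A/px, otherwise to 8 A/px.

    Linear interpolation; the output carries the new pixel size.
    """
    if modality not in ("tomogram", "micrograph"):
        raise ValueError("modality must be 'tomogram' or 'micrograph'")
    if img.pixel_size <= 0:
        raise ValueError("pixel size must be known and positive")
    if modality == "tomogram":
        target = 15.0
    else:
        target = 4.0 if img.pixel_size < 10.0 else 8.0
    zoom = img.pixel_size / target
    data = ndimage.zoom(img.data.astype(float), zoom, order=1)
    return VolumeImage(data, target, "raw")
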