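import numpy as np
import pytest

from tomotrace.core import PointCloud
from tomotrace.simulate import SimSpec, augment_cloud, simulate_filaments


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cloud_3d(rng):
    return PointCloud(rng.uniform(0, 100, size=(6, 3)))


@pytest.fixture
def chain_cloud():
    """A clean 2-instance ordered chain cloud (no augmentation)."""
    spec = SimSpec(n_instances=2, points_per_instance=(8, 12),
                   jiggle_amplitude=0.0, noise_fraction=0.0, drop_fraction=0.0,
                   seed=7)
    return simulate_filaments(spec)


@pytest.fixture
def noisy_chain_cloud():
    """An augmented filament cloud with jiggle, clutter and drops."""
    spec = SimSpec(n_instances=3, points_per_instance=(10, 18), seed=21)
    return augment_cloud(simulate_filaments(spec), spec)


def rigid_motion(coords, rng):
    """Random rotation + translation of a 2D/3D point set."""
    d = coords.shape[1]
    if d == 2:
        a = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    else:
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
    t = rng.uniform(-50, 50, size=d)
    return coords @ R.T + t
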