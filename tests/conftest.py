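import numpy as np
import pytest

from zershape.fixtures import ShapeSpec, make_shape
from zershape.structure import RepresentativeAtomSet
from zershape.volume import rasterize, unit_sphere_frame
from zershape.zernike import compute_moments


@pytest.fixture(scope="session")
def blob_atoms() -> RepresentativeAtomSet:
    """Asymmetric 60-point cloud with residue-like masses."""
    rng = np.random.default_rng(42)
    pts = rng.normal(scale=5.0, size=(60, 3)) * np.array([1.6, 1.0, 0.7])
    masses = rng.uniform(57.0, 186.0, size=60)
    return RepresentativeAtomSet(pts, masses)


@pytest.fixture(scope="session")
def blob_moments(blob_atoms):
    """Order-20 moments of the blob at 0.5 A grid (shared, read-only)."""
    vol = rasterize(blob_atoms, 0.5)
    frame = unit_sphere_frame(blob_atoms)
    return compute_moments(vol, frame, 20)


@pytest.fixture(scope="session")
def helix_atoms() -> RepresentativeAtomSet:
    """Chiral, asymmetric helix bundle (well-conditioned normalizations)."""
    return make_shape(ShapeSpec("helix_bundle", n_points=90, size=12.0, seed=3))


def moments_of(atoms, order_max=20, grid_width=0.5):
    vol = rasterize(atoms, grid_width)
    return compute_moments(vol, unit_sphere_frame(atoms), order_max)
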