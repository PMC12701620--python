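import numpy as np
import pytest

from petmass.phantom import LesionSpec, PhantomSpec, make_phantom
from petmass.segmentation import label_components, threshold_segment


@pytest.fixture(scope="session")
def sphere_phantom():
    """Digitized sphere, r = 20 mm, 2 mm isotropic spacing, uniform SUV 8."""
    spec = PhantomSpec(
        grid_shape=(40, 40, 40),
        spacing_mm=(2.0, 2.0, 2.0),
        background_suv=1.0,
        lesions=[LesionSpec(shape="sphere", center_mm=(40.0, 40.0, 40.0), radius_mm=20.0, suv_peak=8.0)],
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def cuboid_phantom():
    """Grid-aligned 10x10x10-voxel cuboid at 2 mm spacing, uniform SUV 6."""
    # half-edges 10 mm; center chosen so exactly voxels 5..14 fall inside
    spec = PhantomSpec(
        grid_shape=(24, 24, 24),
        spacing_mm=(2.0, 2.0, 2.0),
        background_suv=0.5,
        lesions=[
            LesionSpec(shape="cuboid", center_mm=(19.0, 19.0, 19.0), radius_mm=(9.5, 9.5, 9.5), suv_peak=6.0)
        ],
    )
    return make_phantom(spec)


def random_phantom(seed: int, n_lesions: int = 5, grid: int = 28, spacing=(2.0, 2.0, 2.0)):
    """Small random multi-lesion phantom for oracle batteries."""
    rng = np.random.default_rng(seed)
    extent = (np.asarray([grid] * 3) - 1) * np.asarray(spacing)
    lesions = []
    for _ in range(n_lesions):
        r = rng.uniform(3.0, 9.0)
        center = rng.uniform(r, extent - r)
        lesions.append(
            LesionSpec(shape="sphere", center_mm=tuple(center), radius_mm=float(r), suv_peak=8.0)
        )
    spec = PhantomSpec(
        grid_shape=(grid, grid, grid),
        spacing_mm=spacing,
        background_suv=1.0,
        lesions=lesions,
        seed=seed,
    )
    return make_phantom(spec)


def segment_phantom(volume, threshold=4.0, connectivity=26):
    mask = threshold_segment(volume, threshold)
    return label_components(mask, volume.spacing_mm, volume.origin_mm, connectivity)
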