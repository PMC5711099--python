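import numpy as np
import pytest
from scipy import ndimage

from mtvbench import (
    BinaryMask,
    ImageGrid,
    LesionSpec,
    PhantomSpec,
    generate_phantom,
)


@pytest.fixture
def pet_grid():
    return ImageGrid((20, 20, 20), (4.0, 4.0, 4.0))


@pytest.fixture
def plateau_case(pet_grid):
    """Noiseless, unblurred sphere r=10 mm, uptake 8 on background 1."""
    spec = PhantomSpec(
        lesions=(LesionSpec((40.0, 40.0, 40.0), (10.0, 10.0, 10.0), 8.0),),
        pet_grid=pet_grid,
        psf_fwhm=0.0,
        noise_sd_at_background=0.0,
    )
    return generate_phantom(spec)


@pytest.fixture
def noisy_case(pet_grid):
    spec = PhantomSpec(
        lesions=(LesionSpec((40.0, 40.0, 40.0), (12.0, 10.0, 11.0), 6.0),),
        pet_grid=pet_grid,
        psf_fwhm=7.0,
        noise_sd_at_background=0.1,
        seed=11,
    )
    return generate_phantom(spec)


def random_blob_mask(grid: ImageGrid, rng: np.random.Generator, q: float = 0.85) -> BinaryMask:
    """Largest 26-connected component of thresholded smoothed noise."""
    f = ndimage.gaussian_filter(rng.standard_normal(grid.shape), 1.5)
    mem = f > np.quantile(f, q)
    lab, n = ndimage.label(mem, structure=np.ones((3, 3, 3), bool))
    sizes = ndimage.sum_labels(np.ones(grid.shape), lab, np.arange(1, n + 1))
    return BinaryMask(grid, lab == (1 + int(np.argmax(sizes))))
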