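import numpy as np
import pytest

from faasym.phantom import PhantomSpec, Tube, generate_symmetric_template
from faasym.volio import VolumetricImage, make_grid_affine


@pytest.fixture(scope="session")
def small_spec():
    """Small noiseless phantom spec used by several unit tests."""
    return PhantomSpec(
        grid_shape=(33, 39, 33), voxel_size_mm=4.0, noise_sigma=0.0,
        warp_amplitude_mm=0.0, affine_jitter_mm=0.0, affine_jitter_rad=0.0,
        affine_jitter_scale=0.0,
    )


@pytest.fixture(scope="session")
def small_templates(small_spec):
    return generate_symmetric_template(small_spec)


@pytest.fixture(scope="session")
def tube_template():
    """Single straight tube (radius 3 voxels) on a small grid, no texture."""
    spec = PhantomSpec(
        grid_shape=(33, 39, 33), voxel_size_mm=4.0, noise_sigma=0.0,
        texture_amplitude=0.0,
        tract_set=[Tube((-20.0, -60.0, 0.0), (-20.0, 60.0, 0.0), 12.0, 0.7)],
    )
    fa, b0 = generate_symmetric_template(spec)
    return spec, fa


@pytest.fixture
def tiny_image():
    """A deterministic smooth 3D image on a flip-closed 4 mm grid."""
    shape = (21, 25, 21)
    affine = make_grid_affine(shape, 4.0)
    rng = np.random.default_rng(0)
    from scipy import ndimage

    data = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    data = (data - data.min()) / np.ptp(data)
    return VolumetricImage(data, affine)
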