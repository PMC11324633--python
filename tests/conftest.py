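import numpy as np
import pytest

from spectsub.phantom import PhantomConfig, TumorSpec
from spectsub.system import ProjectionSet, SystemGeometry, SystemModel
from spectsub.volumes import AttenuationVolume


@pytest.fixture(scope="session")
def tiny_config() -> PhantomConfig:
    """A coarse two-tumor phantom small enough for repeated reconstruction."""
    return PhantomConfig(
        grid_shape=(16, 16, 8),
        voxel_size_mm=24.0,
        liver_center_mm=(0.0, 0.0, 0.0),
        liver_semi_axes_mm=(140.0, 110.0, 70.0),
        body_center_mm=(0.0, 0.0),
        body_semi_axes_mm=(180.0, 150.0),
        tumors=[
            TumorSpec((0.0, 30.0, 0.0), 60.0, 2.0, 4.0),
            TumorSpec((0.0, -50.0, 0.0), 60.0, 5.0, 1.0),
        ],
    )


@pytest.fixture(scope="session")
def tiny_geometry() -> SystemGeometry:
    return SystemGeometry(n_views=16)


@pytest.fixture(scope="session")
def tiny_model(tiny_config, tiny_geometry) -> SystemModel:
    from spectsub.phantom import build_attenuation

    return SystemModel(build_attenuation(tiny_config), tiny_geometry)


@pytest.fixture(scope="session")
def tiny_scans(tiny_config, tiny_geometry, tiny_model):
    """Noise-free and noisy (seeded) scan pairs of the tiny phantom."""
    from spectsub.phantom import build_phantom_pair
    from spectsub.system import add_poisson_noise

    pre, post, diff = build_phantom_pair(tiny_config)
    angles = tiny_geometry.angles_deg
    f_pre = ProjectionSet(tiny_model.forward(pre.values), angles)
    f_diff = ProjectionSet(tiny_model.forward(diff.values), angles)
    f_post = ProjectionSet(f_pre.counts + f_diff.counts, angles)
    return {
        "f_pre": f_pre,
        "f_diff": f_diff,
        "f_post": f_post,
        "y_pre": add_poisson_noise(f_pre, 11),
        "y_post": add_poisson_noise(f_post, 12),
        "y_diff": add_poisson_noise(f_diff, 13),
    }


@pytest.fixture()
def flat_model():
    """No attenuation, no PSF, 24 views on an 8x8x4 grid."""
    mu = AttenuationVolume(np.zeros((8, 8, 4)), 20.0)
    geom = SystemGeometry(n_views=24, psf_fwhm0_mm=0.0, psf_slope_mm_per_mm=0.0)
    return SystemModel(mu, geom)
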