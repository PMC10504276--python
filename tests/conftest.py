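import numpy as np
import pytest

from doctk.phantom import PhantomSpec, build_kidney_phantom


def make_uniform_phantom(
    tau: float,
    static_fraction: float = 0.0,
    snr_db: float = 30.0,
    shape: tuple[int, int, int] = (64, 256, 1),
    seed: int = 1,
    backscatter: float = 1.0,
    psf_fwhm_px: float = 2.5,
) -> PhantomSpec:
    """Homogeneous tissue block with a surface at z=0: the closed-form
    oracle workhorse (every voxel shares tau, f and backscatter)."""
    nz, nx, ny = shape
    surface = np.zeros((nx, ny), dtype=np.int64)
    air = np.zeros(shape, dtype=bool)
    masks = {"air": air, "tissue": ~air}
    noise_variance = backscatter * 10 ** (-snr_db / 10) if backscatter > 0 else 1.0
    return PhantomSpec(
        grid_shape=shape,
        pixel_pitch_um=(7.24, 3000.0 / 512, 3000.0 / 128),
        surface_height=surface,
        structure_masks=masks,
        tau_map=np.full(shape, tau),
        static_fraction_map=np.full(shape, static_fraction),
        backscatter_map=np.full(shape, backscatter),
        noise_variance=noise_variance,
        seed=seed,
        psf_fwhm_px=psf_fwhm_px,
    )


@pytest.fixture(scope="session")
def normal_phantom():
    return build_kidney_phantom("normal", seed=7)


@pytest.fixture(scope="session")
def obstructed_2w_phantom():
    return build_kidney_phantom("obstructed_2w", seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
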