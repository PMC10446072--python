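import numpy as np
import pytest

from pseudoislet3d import SimulationConfig, VoxelGeometry, simulate_dataset


@pytest.fixture
def iso_geometry():
    """Isotropic 0.5 µm voxels."""
    return VoxelGeometry(pixel_size_xy=0.5, z_step=0.5)


@pytest.fixture
def aniso_geometry():
    """Anisotropic voxels close to a real spinning-disk acquisition."""
    return VoxelGeometry(pixel_size_xy=0.5, z_step=0.8)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def clean_sim_config(n_cells=30, seed=7, **overrides):
    """Small noise-free, artifact-free simulation (the 'easy' limit)."""
    params = dict(
        n_cells=n_cells, aggregate_radius=20.0, cell_radius=3.5,
        nucleus_radius=3.0, contact_fraction=1.0, ecm_fibre_count=4,
        attenuation_length=np.inf, psf_sigma_xy=0.0, psf_sigma_z=0.0,
        background_amplitude=0.0, noise_photons=0.0, noise_read_sigma=0.0,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def clean_dataset():
    """One cached small noise-free pseudoislet stack plus truth (grid frame)."""
    cfg = clean_sim_config()
    geometry = VoxelGeometry(pixel_size_xy=0.5, z_step=0.5)
    stack, truth = simulate_dataset(cfg, geometry)
    return cfg, geometry, stack, truth
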