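import numpy as np
import pytest

from dbspectra.acquisition import build_default_scheme
from dbspectra.dbsi import DBSIConfig
from dbspectra.signal_model import (
    AnisotropicComponent,
    IsotropicSpectrum,
    VoxelTruth,
)

Z = np.array([0.0, 0.0, 1.0])


@pytest.fixture(scope="session")
def scheme():
    """Default 25-direction multi-b scheme plus one b=0."""
    return build_default_scheme()


@pytest.fixture(scope="session")
def dbsi_config():
    return DBSIConfig()


def make_voxel(direction, lambda_par, lambda_perp, fiber_fraction,
               iso_ds=(), iso_ws=(), s0=1.0):
    """Convenience constructor for a normalized VoxelTruth."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    return VoxelTruth(
        aniso=AnisotropicComponent(direction, lambda_par, lambda_perp, fiber_fraction),
        iso=IsotropicSpectrum(list(iso_ds), list(iso_ws)),
        s0=s0,
    )


def random_fiber_voxel(rng, two_pool=True):
    """Random anisotropic voxel within the inversion bounds.

    Fiber diffusivities span the white-matter range the solver is
    bounded to, with enough anisotropy that the voxel carries
    orientation information; isotropic mass sits in the phantom's two
    default pools (restricted 0.15, non-restricted 1.5 μm²/ms).
    """
    v = rng.standard_normal(3)
    v /= np.linalg.norm(v)
    lambda_par = rng.uniform(1.0, 2.6)
    lambda_perp = rng.uniform(0.05, 0.5)
    ff = rng.uniform(0.5, 0.95)
    split = rng.uniform(0.0, 1.0)
    iso = 1.0 - ff
    if two_pool:
        return make_voxel(v, lambda_par, lambda_perp, ff,
                          iso_ds=(0.15, 1.5), iso_ws=(iso * split, iso * (1 - split)))
    return make_voxel(v, lambda_par, lambda_perp, ff, iso_ds=(1.5,), iso_ws=(iso,))
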