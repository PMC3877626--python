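"""Shared fixtures.

The full-size phantom studies and the calibrated blur are expensive
(tens of seconds each), so they are built once per session and shared
between the unit suite and the acceptance tests.  Small throwaway
grids for projector/phantom unit tests are built per test.
"""

import logging

import numpy as np
import pytest

from petgtm import (
    DEFAULT_PSF_FWHM,
    build_brain_study,
    build_sphere_study,
    calibrate_blur,
    compute_rsf_sinogram_space,
    default_config,
    default_sphere_spec,
    run_accuracy_experiment,
)
from petgtm.model import PVCConfig

# condition-number warnings for the thin-wall sphere systems are expected
logging.getLogger("petgtm.model").setLevel(logging.ERROR)

#: master seed of the deterministic test Monte-Carlo runs
TEST_SEED = 20130435


@pytest.fixture(scope="session")
def sphere_study():
    return build_sphere_study()


@pytest.fixture(scope="session")
def brain_study():
    return build_brain_study()


@pytest.fixture(scope="session")
def calibrated_blur(sphere_study):
    return calibrate_blur(
        DEFAULT_PSF_FWHM,
        grid_shape=sphere_study.pet_shape,
        voxel_size=sphere_study.pet_voxel,
    )


@pytest.fixture(scope="session")
def pvc_config(calibrated_blur):
    return PVCConfig(psf_fwhm=DEFAULT_PSF_FWHM, blur=calibrated_blur)


@pytest.fixture(scope="session")
def sphere_sino_rsfs(sphere_study, pvc_config):
    rsfs = compute_rsf_sinogram_space(
        sphere_study.masks,
        sphere_study.region_names,
        pvc_config.blur,
        sphere_study.pet_voxel,
    )
    # let the experiment fixtures reuse the expensive computation
    pvc_config.rsf_cache[("sinogram-space", tuple(sphere_study.region_names))] = rsfs
    return rsfs


@pytest.fixture(scope="session")
def sphere_accuracy(sphere_study, pvc_config, sphere_sino_rsfs):
    """100-realization accuracy run on the sphere tank (25% noise)."""
    return run_accuracy_experiment(
        sphere_study, n_realizations=100, seed=TEST_SEED, config=pvc_config
    )


@pytest.fixture(scope="session")
def brain_accuracy(brain_study, pvc_config):
    return run_accuracy_experiment(
        brain_study, n_realizations=100, seed=TEST_SEED + 1, config=pvc_config
    )


@pytest.fixture(scope="session")
def noiseless_sphere_study():
    return build_sphere_study(default_sphere_spec(noise_fraction=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
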