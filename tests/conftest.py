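import numpy as np
import pytest

from mrnlm import EmulationParams, MultiReconSet, PhantomSpec, ReconSetting, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)


@pytest.fixture
def small_volume(rng) -> Volume:
    """A random non-negative volume on an anisotropic grid."""
    return Volume(rng.random((9, 9, 5)), spacing=(2.0, 2.0, 3.0))


@pytest.fixture
def small_recons(rng) -> MultiReconSet:
    """Target plus four auxiliaries sharing structure with independent noise."""
    base = rng.random((9, 9, 5)) + 0.5
    noisy = lambda: np.clip(base + 0.05 * rng.standard_normal(base.shape), 0, None)
    target = Volume(noisy(), spacing=(2.0, 2.0, 3.0))
    aux = tuple(Volume(noisy(), spacing=(2.0, 2.0, 3.0)) for _ in range(4))
    return MultiReconSet(target, aux)


@pytest.fixture
def small_phantom_spec() -> PhantomSpec:
    """A shrunken two-sphere phantom for fast end-to-end unit tests."""
    return PhantomSpec(
        cylinder_radius_mm=40.0,
        cylinder_height_mm=48.0,
        sphere_diameters_mm=(8.0, 12.0),
        sphere_centers_mm=((-15.0, 0.0, 0.0), (15.0, 0.0, 0.0)),
    )


@pytest.fixture
def small_emulation() -> EmulationParams:
    return EmulationParams(psf_fwhm_mm=4.0, noise_sigma=0.1, seed=7)


@pytest.fixture
def small_aux_settings():
    return (ReconSetting(2, 24), ReconSetting(3, 14), ReconSetting(4, 12))
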