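import numpy as np
import pytest

import coeruleus as co


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom_params():
    """A reduced phantom lattice for fast per-test generation."""
    return co.NmPhantomParams(
        shape=(12, 32, 32),
        nuclei={
            "lc": co.synth.NucleusDef(center=(6, 10, 9), decay_mm=1.2,
                                      template_radius_mm=1.0,
                                      amplitude=1.15),
            "vta_snc": co.synth.NucleusDef(center=(6, 10, 22),
                                           decay_mm=1.5,
                                           template_radius_mm=1.5,
                                           amplitude=1.10),
        },
        control_box=(slice(4, 9), slice(22, 28), slice(8, 24)),
        noise_sd=2.0)


@pytest.fixture(scope="session")
def quiet_bold_params():
    """Low-noise BOLD simulation with a small target grid."""
    return co.BoldSimParams(target_shape=(3, 3, 3), physio_amp=0.0,
                            motion_amp=0.0, noise_sd=0.2)
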