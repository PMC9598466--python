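import numpy as np
import pytest

from noseguard import make_head_phantom, make_template


@pytest.fixture(scope="session")
def template():
    return make_template()


@pytest.fixture(scope="session")
def phantom(template):
    """Default-amplitude phantom with intensity noise (seed fixed)."""
    return make_head_phantom(template, deform_amplitude_mm=4.0, seed=1)


@pytest.fixture(scope="session")
def noiseless_phantom(template):
    """Phantom without intensity noise for exact-recovery checks."""
    return make_head_phantom(
        template, deform_amplitude_mm=3.0, seed=7, intensity_noise_sd=0.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
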