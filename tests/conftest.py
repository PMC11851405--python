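import numpy as np
import pytest

from recalseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One 32^3 phantom with the default spec, fixed seed."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom: intensities are exactly the class means."""
    return generate_phantom(PhantomSpec(noise_sd=0.0, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
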