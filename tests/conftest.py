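import numpy as np
import pytest

from petmtv.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom (blur + noise + hot bladder), rendered once."""
    spec = PhantomSpec(rng_seed=42)
    pet, labels = make_phantom(spec)
    return spec, pet, labels


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free blurred phantom with a cool bladder: tumour dominates."""
    spec = PhantomSpec(rng_seed=7, noise_sd_suv=0.0, bladder_suv=4.0)
    pet, labels = make_phantom(spec)
    return spec, pet, labels


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
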