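import numpy as np
import pytest

from hipposeg import ModelParams, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def easy_phantom():
    """Easy two-Gaussian phantom (means 160/80, stds 10), fixed noise seed."""
    spec = PhantomSpec(name="easy", rng_seed=0)
    image, truth, seed = generate_phantom(spec)
    return image, truth, seed


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
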