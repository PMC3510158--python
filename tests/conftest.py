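import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def normal_sample(rng):
    """A generic length-like sample: 300 draws around 400 mm."""
    return rng.normal(400.0, 80.0, 300)
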