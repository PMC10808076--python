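import numpy as np
import pytest

from gsop.core import StructuredDriftModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_model():
    """A d=3 structured drift model with random (seeded) weights."""
    return StructuredDriftModel(d=3, d_star=1, m=8, u_hidden=(16,),
                                a_hidden=(8, 8), seed=7)
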