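import numpy as np
import pytest

from gainsweep.activations import ActivationSpec, GlobalGainState
from gainsweep.images import StyleParams


@pytest.fixture(scope="session")
def tiny_style():
    """Small images keep generator tests fast."""
    return StyleParams(image_size=16)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(params=["rectifier", "saturating"])
def activation_spec(request):
    return ActivationSpec(kind=request.param)
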