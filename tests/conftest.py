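import numpy as np
import pytest

from safebn import study


@pytest.fixture
def core_net():
    """The calibrated three-node study network."""
    return study.core_network()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
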