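import numpy as np
import pytest

from cordisp.protocol import default_protocol


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
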