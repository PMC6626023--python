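import numpy as np
import pytest

from somamosaic.signatures import synthetic_catalog


@pytest.fixture(scope="session")
def catalog():
    return synthetic_catalog()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
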