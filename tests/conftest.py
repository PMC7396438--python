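import numpy as np
import pytest

from xlinkdock.synthetic_data import make_block_complex, make_helix_backbone


@pytest.fixture(scope="session")
def block_system():
    return make_block_complex(seed=1)


@pytest.fixture(scope="session")
def helix10():
    return make_helix_backbone(10)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
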