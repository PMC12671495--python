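import numpy as np
import pytest

from psiikin import make_preset


@pytest.fixture(scope="session")
def wt():
    return make_preset("WT")


@pytest.fixture(scope="session")
def t_grid():
    return np.arange(0.0, 2.0001, 1e-3)
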