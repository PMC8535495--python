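import numpy as np
import pytest

from tdsboot import builtin_model


@pytest.fixture(scope="session")
def case1():
    return builtin_model(1)


@pytest.fixture(scope="session")
def case2():
    return builtin_model(2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20211015)
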