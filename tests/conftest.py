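import numpy as np
import pytest

from minidftb.fixtures import build_suite


@pytest.fixture(scope="session")
def suite():
    return build_suite()


@pytest.fixture(scope="session")
def params(suite):
    return suite.params


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250606)
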