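import numpy as np
import pytest

from robustcorr import anscombe


@pytest.fixture(scope="session")
def quartet():
    """The four Anscombe pairs as [(x, y), ...]."""
    return anscombe()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
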