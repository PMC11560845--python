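import numpy as np
import pytest

from symbiopop.model import TransmissionParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def washout_params():
    """Ancestral-pair regime: positives decline without selection."""
    return TransmissionParams(g=0.88, e=0.69, p0=0.29)


def random_params(rng, allow_zero_e=False):
    g = rng.uniform(0, 1)
    e = rng.uniform(0.01 if not allow_zero_e else 0.0, 1)
    p0 = rng.uniform(0, 1)
    return TransmissionParams(g=g, e=e, p0=p0)
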