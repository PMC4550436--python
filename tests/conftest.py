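import numpy as np
import pytest

from wavestdp.kernels import BurstProfile, EPSPKernel, STDPRule


@pytest.fixture
def asym_rule():
    return STDPRule.asymmetric()


@pytest.fixture
def sym_rule():
    return STDPRule.symmetric()


@pytest.fixture
def boxcar_burst():
    return BurstProfile("boxcar", 50.0, 0.1)


@pytest.fixture
def epsp():
    return EPSPKernel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
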