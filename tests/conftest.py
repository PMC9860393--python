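import numpy as np
import pytest

from gradespike import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def template():
    return synth.EapTemplateParams()


@pytest.fixture
def kernel():
    return synth.KernelParams()


@pytest.fixture
def classes():
    return synth.SpikeClassParams()
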