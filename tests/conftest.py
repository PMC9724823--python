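import numpy as np
import pytest

from ssdanova import build_pair, parse_hypothesis


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def h0_k3():
    return parse_hypothesis("mu1=mu2=mu3", 3)


@pytest.fixture
def ha_k3():
    return parse_hypothesis("Ha", 3)


@pytest.fixture
def ordered_k3():
    return parse_hypothesis("mu3>mu2>mu1", 3)


@pytest.fixture
def pair_null_vs_ha(h0_k3, ha_k3):
    return build_pair(h0_k3, ha_k3)
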