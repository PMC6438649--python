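import numpy as np
import pytest

from valleycross import AcceptanceRule, ValleySpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sswm_rule():
    return AcceptanceRule.sswm(beta=1.0, N=2)


@pytest.fixture
def metropolis_rule():
    return AcceptanceRule.metropolis(alpha=1.0)


@pytest.fixture
def small_valley():
    """The shallow reference valley: effective length 3."""
    return ValleySpec(l1=2, l2=2, d1=1.0, d2=2.0)


@pytest.fixture
def standard_valley():
    return ValleySpec(l1=2, l2=2, d1=2.0, d2=4.0)
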