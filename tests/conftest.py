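import numpy as np
import pytest

from mhcamplicon import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_allele_set(rng):
    """Ten distinct 350-bp alleles differing at <= 18 sites."""
    return simulate.gen_allele_set("DQA", 10, 350, 18, rng)


@pytest.fixture
def two_allele_set():
    """Hand-built pair of 40-bp alleles differing at three known sites."""
    a = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
    b = a[:5] + "G" + a[6:20] + "C" + a[21:30] + "T" + a[31:]
    assert sum(x != y for x, y in zip(a, b)) == 3
    return simulate.AlleleSet("TEST", ["T*01", "T*02"], [a, b])
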