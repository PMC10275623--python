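import numpy as np
import pytest

from revcorr import make_mel_partition, synthesize_target


@pytest.fixture(scope="session")
def partition():
    """The default 8-bin mel partition of [100, 13000] Hz."""
    return make_mel_partition(100.0, 13000.0, 8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def buzzing_target(partition):
    return synthesize_target(
        "buzzing-like", partition, rng=np.random.default_rng(101)
    )


@pytest.fixture(scope="session")
def roaring_target(partition):
    return synthesize_target(
        "roaring-like", partition, rng=np.random.default_rng(102)
    )
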