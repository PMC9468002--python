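import numpy as np
import pytest

from dbgps.strand import StrandLayout, build_strand
from dbgps.dna import arr_to_seq


@pytest.fixture(scope="session")
def layout():
    return StrandLayout()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_random_pool(n, seed=0, layout=None):
    """Designed strands with uniform random payloads."""
    layout = layout or StrandLayout()
    rng = np.random.default_rng(seed)
    return [
        build_strand(
            m, arr_to_seq(rng.integers(0, 4, size=layout.payload_len, dtype=np.uint8)), layout
        )
        for m in range(n)
    ]


@pytest.fixture(scope="session")
def small_pool():
    return make_random_pool(30, seed=7)
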