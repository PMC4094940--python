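import numpy as np
import pytest

from retrosite import make_genome


@pytest.fixture(scope="session")
def genome():
    """Small two-chromosome genome shared by read-only tests."""
    return make_genome(n_chroms=2, chrom_len=1_000_000, n_genes=50, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
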