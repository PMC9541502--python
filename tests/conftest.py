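import numpy as np
import pytest

from batchsw import build_standard_sw, from_icc_cac, make_batched


@pytest.fixture
def staircase6():
    return build_standard_sw(6)


@pytest.fixture
def pact_design(staircase6):
    """Two identical batches of the 5-sequence, 6-period staircase."""
    return make_batched(staircase6, n_batches=2, overlap=0, clusters_per_sequence=1)


@pytest.fixture
def hh_model():
    return from_icc_cac("hussey_hughes", 0.05)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
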