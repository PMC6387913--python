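import numpy as np
import pytest

from histone_bn.matrix import ModificationMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, mark_names=None, **kwargs):
    """Small-matrix helper: rows become exon_0, exon_1, ..."""
    values = np.asarray(values)
    if mark_names is None:
        mark_names = [f"mk{j}" for j in range(values.shape[1])]
    ids = [f"exon_{i}" for i in range(values.shape[0])]
    return ModificationMatrix(ids, list(mark_names), values, **kwargs)


@pytest.fixture
def copy_pair_matrix(rng):
    """Two columns, B an exact copy of A (n=500)."""
    x = rng.integers(0, 2, 500).astype(np.uint8)
    return make_matrix(np.column_stack([x, x]), ["A", "B"])


@pytest.fixture
def random_binary_matrix(rng):
    """Four independent Bernoulli(0.5) columns, n=200."""
    return make_matrix(rng.integers(0, 2, (200, 4)).astype(np.uint8))
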