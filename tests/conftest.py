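import numpy as np
import pytest
import scipy.sparse as sp

from chromstate import CountMatrix


@pytest.fixture
def small_counts():
    """Deterministic 6-peak x 4-cell integer count matrix."""
    rng = np.random.default_rng(42)
    counts = rng.poisson(2.0, size=(6, 4)) + 1
    return CountMatrix(
        sp.csr_matrix(counts),
        [f"peak{i}" for i in range(6)],
        [f"cell{j}" for j in range(4)],
    )


def make_counts(array):
    array = np.asarray(array)
    return CountMatrix(
        sp.csr_matrix(array),
        [f"peak{i}" for i in range(array.shape[0])],
        [f"cell{j}" for j in range(array.shape[1])],
    )
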