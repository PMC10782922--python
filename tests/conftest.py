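import numpy as np
import pytest
import scipy.sparse as sp

from cofea import CountMatrix, Peak


def make_count_matrix(values, labels=None) -> CountMatrix:
    """Build a CountMatrix from a dense array, with synthetic peaks/barcodes."""
    values = np.asarray(values)
    p, n = values.shape
    peaks = [Peak("chr1", i * 1000, i * 1000 + 500) for i in range(p)]
    barcodes = [f"bc{j:04d}" for j in range(n)]
    if labels is not None:
        labels = {bc: lab for bc, lab in zip(barcodes, labels)}
    return CountMatrix(
        values=sp.csr_matrix(values), peaks=peaks, barcodes=barcodes, labels=labels
    )


def random_count_matrix(p, n, density=0.2, seed=0, max_count=3) -> CountMatrix:
    rng = np.random.default_rng(seed)
    values = rng.integers(1, max_count + 1, size=(p, n)) * (
        rng.random((p, n)) < density
    )
    return make_count_matrix(values)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_cm():
    # every peak and cell nonzero somewhere
    return make_count_matrix(
        [
            [1, 0, 2, 0],
            [0, 1, 1, 1],
            [2, 2, 0, 1],
            [1, 0, 0, 3],
        ]
    )
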