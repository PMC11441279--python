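import numpy as np
import pytest

from circdrug import generate_synthetic_dataset
from circdrug.similarity import SimilarityKind, SimilarityMatrix


@pytest.fixture(scope="session")
def tiny_dataset():
    """40 circRNAs x 30 drugs with planted 4-cluster structure."""
    return generate_synthetic_dataset(
        n_circ=40, n_drug=30, n_clusters=4, seq_len=60, fp_len=64, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_similarity(n: int, seed: int, kind=SimilarityKind.fused) -> SimilarityMatrix:
    r = np.random.default_rng(seed)
    W = r.random((n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 1.0)
    return SimilarityMatrix(W, tuple(f"e{i}" for i in range(n)), kind)
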