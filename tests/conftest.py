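import numpy as np
import pytest

from snakedragons.matrix_io import CorrelationMatrix, MatrixCollection, synth_labels


def random_correlation(q: int, rng: np.random.Generator) -> CorrelationMatrix:
    """Valid random correlation matrix via a Wishart-type construction."""
    G = rng.standard_normal((q, q + 2))
    W = G @ G.T
    d = np.sqrt(np.diag(W))
    V = W / np.outer(d, d)
    np.fill_diagonal(V, 1.0)
    return CorrelationMatrix(synth_labels(q), V)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_collection(rng):
    q, N = 5, 6
    mats = [random_correlation(q, rng) for _ in range(N)]
    for i, m in enumerate(mats):
        m.name = f"obj{i + 1}"
    return MatrixCollection([m.name for m in mats], mats)


@pytest.fixture(scope="session")
def prototype_pair():
    """One prototype pair shared by the slower simulation tests."""
    from snakedragons.simulate import generate_prototype_pair

    A, B, meta = generate_prototype_pair(q=36, target_snr_floor=1.2, rng_seed=1)
    return A, B, meta
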