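import numpy as np
import pytest

from copulasim import CountMatrix


def toy_counts(values, gene_ids=None, sample_ids=None) -> CountMatrix:
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(p)]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(n)]
    return CountMatrix(values, gene_ids, sample_ids)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def normal_reference():
    """Small correlated normal-family reference with known truth."""
    from copulasim import make_reference
    return make_reference(p=120, n=80, k_true=2, family="normal", seed=7)
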