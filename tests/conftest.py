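import numpy as np
import pytest
import scipy.sparse as sp

from plaid import ExpressionMatrix, GeneSetCollection


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_expression():
    """3 genes x 2 samples, dense."""
    return ExpressionMatrix(
        np.array([[2.0, 4.0], [4.0, 8.0], [99.0, 1.0]]),
        ["g1", "g2", "g3"],
        ["s1", "s2"],
    )


@pytest.fixture
def tiny_collection():
    return GeneSetCollection.from_dict({"A": ["g1", "g2"], "B": ["g2", "g3"]})


def random_collection(rng, n_sets, universe, lo=3, hi=10):
    """Random duplicate-free sets as a plain dict factory (order-preserving)."""
    sets = {}
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets[f"SET{k:04d}"] = [universe[i] for i in members]
    return GeneSetCollection.from_dict(sets)


@pytest.fixture
def random_dense(rng):
    """200 genes x 30 samples continuous log-intensity matrix plus 40 sets."""
    p, n = 200, 30
    ids = [f"g{i:04d}" for i in range(p)]
    X = ExpressionMatrix(
        rng.normal(3.0, 1.0, size=(p, n)),
        ids,
        [f"s{j:03d}" for j in range(n)],
    )
    return X, random_collection(rng, 40, ids, lo=5, hi=30)


def to_sparse(X: ExpressionMatrix) -> ExpressionMatrix:
    return ExpressionMatrix(
        sp.csr_array(X.matrix), list(X.feature_ids), list(X.sample_ids), X.value_kind
    )
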