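"""Shared fixtures: small association/similarity instances built in memory."""

import numpy as np
import pytest

from cda_netfuse.core_data import AssociationMatrix, HyperParams, SimilarityMatrix


def random_similarity(k: int, rng: np.random.Generator, ids=None) -> SimilarityMatrix:
    """Random symmetric similarity with unit diagonal, values in [0, 1]."""
    a = rng.random((k, k))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return SimilarityMatrix(ids or [f"x{i}" for i in range(k)], a)


def random_association(m: int, n: int, rng: np.random.Generator, density: float = 0.4) -> AssociationMatrix:
    vals = (rng.random((m, n)) < density).astype(float)
    # guarantee at least one association so downstream models have signal
    if vals.sum() == 0:
        vals[rng.integers(m), rng.integers(n)] = 1.0
    return AssociationMatrix([f"c{i}" for i in range(m)], [f"d{j}" for j in range(n)], vals)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return HyperParams()


@pytest.fixture
def tiny_assoc():
    """2 circRNAs x 2 diseases: c1-{d1,d2}, c2-{d2}."""
    return AssociationMatrix(["c1", "c2"], ["d1", "d2"], [[1, 1], [0, 1]])


@pytest.fixture
def tiny_sem():
    return SimilarityMatrix(["d1", "d2"], [[1.0, 0.3], [0.3, 1.0]])
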