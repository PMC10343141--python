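import numpy as np
import pytest
from hypothesis import strategies as st

import composkern as ck


def random_simplex(rng, n, p, sparsity=0.0):
    """Random (optionally sparse) simplex points; every row keeps at
    least one positive entry."""
    V = rng.gamma(0.5, size=(n, p))
    if sparsity > 0:
        mask = rng.random((n, p)) < sparsity
        keep = rng.integers(0, p, size=n)
        mask[np.arange(n), keep] = False
        V = np.where(mask, 0.0, V)
    V[V.sum(axis=1) == 0, 0] = 1.0
    return V / V.sum(axis=1, keepdims=True)


@st.composite
def simplex_vectors(draw, min_p=2, max_p=8, interior=False):
    p = draw(st.integers(min_p, max_p))
    lo = 1e-3 if interior else 0.0
    vals = draw(st.lists(st.floats(lo, 1.0), min_size=p, max_size=p))
    v = np.asarray(vals)
    if v.sum() <= 0:
        v = np.ones(p)
    return v / v.sum()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    return ck.CompositionTable(random_simplex(rng, 20, 5))


@pytest.fixture
def example_beta():
    return np.array([2.0, -1.0, -1.0, 0.0])


@pytest.fixture
def example_function(example_beta):
    def f(rows):
        return np.log(np.atleast_2d(rows)) @ example_beta
    return f
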