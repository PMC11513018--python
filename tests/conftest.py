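import numpy as np
import pytest

from scdrmae.types import OmicsMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_counts(rng):
    """A 30-cell x 12-gene nonnegative count matrix with no zero rows."""
    counts = rng.poisson(3.0, size=(30, 12)).astype(float)
    counts[:, 0] += 1  # guarantee nonzero library sizes
    return OmicsMatrix(counts, modality="rna")


def finite_difference_grad(f, x, eps=1e-6):
    """Central finite differences of a scalar function of an ndarray."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        hi = f(x)
        x[i] = orig - eps
        lo = f(x)
        x[i] = orig
        g[i] = (hi - lo) / (2 * eps)
    return g
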