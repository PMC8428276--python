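import numpy as np
import pytest

from treetrace.matrix import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def counts_matrix(rng):
    """Small random counts matrix (12 cells x 8 features)."""
    values = rng.poisson(3.0, size=(12, 8)).astype(float)
    values[0, :6] = 0  # a low-complexity cell
    values[:, 7] = 0
    values[0, 7] = 1  # a feature seen in one cell only
    return ExpressionMatrix(
        values,
        [f"c{i}" for i in range(12)],
        [f"g{j}" for j in range(8)],
        layer="counts",
    )


@pytest.fixture
def two_blobs(rng):
    """Two well-separated Gaussian blobs in 5-D, 40 cells each."""
    a = rng.normal(0.0, 0.5, size=(40, 5))
    b = rng.normal(0.0, 0.5, size=(40, 5)) + 20.0
    coords = np.vstack([a, b])
    labels = np.array([0] * 40 + [1] * 40)
    return coords, labels
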