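import numpy as np
import pytest

from lsirm import (
    FitOptions,
    GeneratorConfig,
    ResponseMatrix,
    fit_pjml,
    generate,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_matrix(rng):
    """Small partially observed binary matrix with guaranteed row/col coverage."""
    values = rng.integers(0, 2, (8, 6))
    mask = rng.random((8, 6)) < 0.85
    mask[:, 0] = True
    mask[0, :] = True
    return ResponseMatrix(values, mask)


@pytest.fixture(scope="session")
def medium_fit():
    """One moderate pJML fit on synthetic data, shared across tests."""
    Y, truth = generate(GeneratorConfig(N=400, J=24, D=2, seed=11))
    fit = fit_pjml(Y, FitOptions(D=2, seed=11))
    return Y, truth, fit


def random_parameters(rng, N, J, D, scale=0.6):
    theta = rng.normal(0, scale, N)
    beta = rng.normal(0, scale, J)
    Z = rng.normal(0, scale, (N, D))
    W = rng.normal(0, scale, (J, D))
    return theta, beta, Z, W
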