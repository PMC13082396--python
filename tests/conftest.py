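import numpy as np
import pytest

from causalde import CountMatrix, DesignMatrix, SimConfig, simulate_pseudobulk


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_sim():
    """A small confounded dataset for fast integration tests."""
    cfg = SimConfig(n=200, p=300, seed=42)
    return simulate_pseudobulk(cfg)


@pytest.fixture()
def toy_counts():
    rng = np.random.default_rng(1)
    Y = rng.poisson(5.0, size=(12, 20))
    Y[:, 0] += 1  # keep column positive
    return CountMatrix(Y)


@pytest.fixture()
def toy_design():
    rng = np.random.default_rng(2)
    A = np.array([0, 1] * 6)
    X = rng.standard_normal((12, 1))
    return DesignMatrix(treatment=A, covariates=X)
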