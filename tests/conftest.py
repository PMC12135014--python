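import numpy as np
import pytest

from selindex.index_core import CovarianceEstimate
from selindex.synthetic import worked_example_fixture


@pytest.fixture
def cov2020() -> CovarianceEstimate:
    """The 2020 Chalk/Yield covariance estimates (worked example)."""
    return worked_example_fixture()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_spd(rng: np.random.Generator, dim: int, jitter: float = 0.5) -> np.ndarray:
    """Random symmetric positive-definite matrix."""
    A = rng.normal(size=(dim, dim))
    return A @ A.T + jitter * dim * np.eye(dim)


def random_cov_pair(rng: np.random.Generator, dim: int) -> CovarianceEstimate:
    """Random (P, C) pair with PD P, PSD C and per-trait h2 in (0, 1)."""
    E = random_spd(rng, dim)
    C = random_spd(rng, dim, jitter=0.1)
    return CovarianceEstimate(traits=[f"t{j}" for j in range(dim)], P=C + E, C=C)
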