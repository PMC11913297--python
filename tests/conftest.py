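import numpy as np
import pytest

from cicfit import GaussianMixtureParams


@pytest.fixture
def std_normal_1d() -> GaussianMixtureParams:
    """Standard normal as a one-component mixture on R."""
    return GaussianMixtureParams.single(0.0, 1.0)


@pytest.fixture
def two_comp_1d() -> GaussianMixtureParams:
    """Well-separated two-component mixture on R (means -3, +3, unit var)."""
    return GaussianMixtureParams(
        weights=np.array([0.5, 0.5]),
        means=np.array([[-3.0], [3.0]]),
        covariances=np.array([[[1.0]], [[1.0]]]),
    )


@pytest.fixture
def wide_proposal_1d() -> GaussianMixtureParams:
    """Broad pilot proposal N(0, 5^2) covering both fixture modes."""
    return GaussianMixtureParams.single(0.0, 25.0)


def random_mixture(rng: np.random.Generator, k: int, p: int) -> GaussianMixtureParams:
    """A random valid mixture for property tests."""
    w = rng.dirichlet(np.ones(k))
    means = rng.normal(scale=3.0, size=(k, p))
    covs = np.empty((k, p, p))
    for j in range(k):
        a = rng.normal(size=(p, p))
        covs[j] = a @ a.T + 0.5 * np.eye(p)
    return GaussianMixtureParams(weights=w, means=means, covariances=covs)
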