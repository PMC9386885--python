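import numpy as np
import pytest

from factorretain.correlation import CorrelationEstimate


def block_corr(sizes, loading, phi=0.0):
    """Exact population correlation matrix for equal-loading blocks.

    Each block is one factor with every item loading ``loading``;
    ``phi`` is the common interfactor correlation.
    """
    J = sum(sizes)
    M = len(sizes)
    Lam = np.zeros((J, M))
    j = 0
    for m, size in enumerate(sizes):
        Lam[j : j + size, m] = loading
        j += size
    Phi = np.full((M, M), phi)
    np.fill_diagonal(Phi, 1.0)
    R = Lam @ Phi @ Lam.T
    np.fill_diagonal(R, 1.0)
    return R


def random_pd_corr(rng, n_items=6, n_factors=3, noise=0.4):
    """A random well-conditioned correlation matrix."""
    L = rng.standard_normal((n_items, n_factors))
    S = L @ L.T + noise * np.eye(n_items)
    d = 1.0 / np.sqrt(np.diag(S))
    return S * d[:, None] * d[None, :]


@pytest.fixture
def rng():
    return np.random.default_rng(20260401)


@pytest.fixture
def three_block_corr():
    """Population matrix of the 7/7/6 three-factor design, loadings 0.8."""
    return block_corr([7, 7, 6], 0.8)


def as_estimate(R, n_obs=1000, kind="pearson"):
    return CorrelationEstimate(R_hat=np.asarray(R, float), kind=kind,
                               n_obs=n_obs)
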