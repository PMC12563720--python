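"""Shared fixtures: small synthetic datasets and short fitted chains."""

import numpy as np
import pytest

from bmfr.config import ModelConfig
from bmfr.data import CovariateTable, ExposurePanel, LongitudinalOutcomes


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def make_small_dataset(
    seed=0, n=30, p=4, q=3, K=2, T=5, L=2, censor=True, missing=True
):
    """Small self-consistent dataset drawn from the generative model."""
    rng = np.random.default_rng(seed)
    Theta = rng.standard_normal((p, K)) * 0.8
    eta = rng.standard_normal((n, K))
    X = eta @ Theta.T + 0.6 * rng.standard_normal((n, p))
    lod = None
    cens = None
    if censor:
        lod = np.quantile(X, 0.06, axis=0)
        cens = X <= lod[None, :]
        X = np.where(cens, lod[None, :], X)
    subj = np.repeat(np.arange(n), 2)
    t_idx = np.concatenate([rng.choice(T, 2, replace=False) for _ in range(n)])
    grid = np.arange(4.0, 4.0 + T)
    B = 0.4 * rng.standard_normal((q, K, T))
    Z = rng.standard_normal((len(subj), L))
    Bc = 0.3 * rng.standard_normal((q, L))
    xi = 0.5 * rng.standard_normal((n, q))
    Y = (
        np.einsum("qkt,rk->rq", B, eta[subj] * 0)  # filled below per record
        + Z @ Bc.T
        + xi[subj]
        + 0.5 * rng.standard_normal((len(subj), q))
    )
    Y += np.einsum("rqk,rk->rq", B[:, :, t_idx].transpose(2, 0, 1), eta[subj])
    miss = np.zeros_like(Y, dtype=bool)
    if missing:
        miss[rng.choice(len(subj), 3, replace=False), 0] = True
    exposures = ExposurePanel(X, lod, cens)
    outcomes = LongitudinalOutcomes(Y, subj, t_idx, grid, miss)
    covariates = CovariateTable(Z)
    return exposures, outcomes, covariates


@pytest.fixture(scope="session")
def small_dataset():
    return make_small_dataset()


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A short fitted chain shared by post-processing and results tests."""
    from bmfr.model import BayesianFactorRegression

    exposures, outcomes, covariates = small_dataset
    config = ModelConfig(
        K=2, H=2, kappa=(2.0, 6.0), n_iter=400, n_burn=200, thin=4, seed=42
    )
    model = BayesianFactorRegression(exposures, outcomes, covariates, config)
    return model.fit()
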