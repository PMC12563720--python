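"""Tiny frozen-block toys shared by the conjugacy-style checks."""

import numpy as np

from bmfr.config import ModelConfig
from bmfr.data import ExposurePanel, LongitudinalOutcomes
from bmfr.sampler import FitData


def build_eta_toy(n=100_000):
    """n replicated subjects with identical exposures and no outcome signal:
    the factor-score conditional is the same Gaussian for every subject."""
    Theta = np.array([[1.2], [-0.7]])
    sigma_x2 = np.array([0.8, 1.5])
    x = np.array([0.9, -0.4])
    config = ModelConfig(K=1, H=1, seed=1, n_iter=2, n_burn=1,
                         iw_S0=np.eye(1), hs_r=1.0)
    rng = np.random.default_rng(0)
    subj = np.repeat(np.arange(n), 1)
    outcomes = LongitudinalOutcomes(
        rng.standard_normal((n, 1)), subj, np.zeros(n, dtype=int),
        np.array([1.0]),
    )
    data = FitData(ExposurePanel(np.tile(x, (n, 1))), outcomes, None)
    return data, config, Theta, sigma_x2, x


def build_censored_toy(n=100_000):
    """Every cell censored at 0 with conditional mean at the bound."""
    config = ModelConfig(K=1, H=1, seed=1, n_iter=2, n_burn=1,
                         iw_S0=np.eye(1), hs_r=1.0)
    lod = np.array([0.0])
    cens = np.ones((n, 1), dtype=bool)
    outcomes = LongitudinalOutcomes(
        np.zeros((n, 1)), np.arange(n), np.zeros(n, dtype=int), np.array([1.0])
    )
    data = FitData(
        ExposurePanel(np.full((n, 1), -0.5), lod, cens), outcomes, None
    )
    return data, config
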