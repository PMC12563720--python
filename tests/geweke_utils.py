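"""Machinery for the Geweke-style joint-distribution check.

Two samplers target the same joint distribution p(params) p(data | params):
(a) forward — params from the priors, data from the likelihood, iid;
(b) successive-conditional — alternately redraw data from the likelihood
and params via one full Gibbs sweep.
If every full conditional is correct, the two produce identical marginal
distributions; mismatched moments flag a block error.
"""

import numpy as np
from scipy import stats

from bmfr.config import ModelConfig
from bmfr.core import gp_kernel_matrix
from bmfr.sampler import (
    FitData,
    update_covariate_block,
    update_eta,
    update_factor_block,
    update_gp_block,
    update_kappa,
    update_subject_block,
)
from bmfr.state import ParameterState


def tiny_config(seed=0):
    # nu_scale is kept small here: the joint test's validity is
    # config-independent, and a tight half-Cauchy keeps the nu^2 excursions
    # short so the Monte-Carlo error of the chain average is honest
    return ModelConfig(
        K=1, H=1, mgp_a1=2.1, mgp_a2=3.1, mgp_v=3.0,
        iw_s0=6.0, iw_S0=np.eye(2), nu_scale=1.0,
        hs_u=0.5, hs_v=0.5, hs_r=0.5,
        kappa=(2.0, 6.0), n_iter=2, n_burn=1, seed=seed,
    )


DIMS = dict(n=5, p=2, q=2, K=1, H=1, T=3, L=1)


def _invgamma(rng, shape, rate):
    return 1.0 / rng.gamma(shape, 1.0 / rate)


def prior_state(config, rng, Z, times):
    """One exact draw of all parameters from the priors."""
    n, p, q, K, H, T, L = (DIMS[k] for k in ("n", "p", "q", "K", "H", "T", "L"))
    delta = np.array(
        [rng.gamma(config.mgp_a1, 1.0)]
        + [rng.gamma(config.mgp_a2, 1.0) for _ in range(K - 1)]
    )
    tau = np.cumprod(delta)
    v = config.mgp_v
    phi = rng.gamma(v / 2.0, 2.0 / v, size=(p, K))
    Theta = rng.standard_normal((p, K)) / np.sqrt(phi * tau[None, :])
    sigma_x2 = _invgamma(rng, config.sigma_x_shape, config.sigma_x_rate * np.ones(p))
    eta = rng.standard_normal((n, K))
    lambda_delta = np.array(
        [rng.gamma(config.mgp_a1, 1.0)]
        + [rng.gamma(config.mgp_a2, 1.0) for _ in range(H - 1)]
    )
    lam_tau = np.cumprod(lambda_delta)
    lambda_phi = rng.gamma(v / 2.0, 2.0 / v, size=(q, H))
    Lambda = rng.standard_normal((q, H)) / np.sqrt(lambda_phi * lam_tau[None, :])
    kappa = float(rng.choice(config.kappa))
    C = gp_kernel_matrix(times, kappa)
    Lc = np.linalg.cholesky(C + 1e-10 * np.eye(T))
    U = np.einsum("ts,hks->hkt", Lc, rng.standard_normal((H, K, T)))
    Sigma_y = stats.invwishart.rvs(config.iw_s0, config.iw_S0, random_state=rng)
    nu_aux = _invgamma(rng, 0.5, 1.0 / config.nu_scale**2)
    nu2 = float(_invgamma(rng, 0.5, 1.0 / nu_aux))
    Ls = np.linalg.cholesky(Sigma_y)
    xi = np.sqrt(nu2) * rng.standard_normal((n, q)) @ Ls.T
    zeta = rng.gamma(config.hs_v, 1.0 / config.hs_r, size=L)
    psi = rng.gamma(config.hs_u, 1.0 / zeta)
    Bc = (rng.standard_normal((L, q)) * np.sqrt(psi)[:, None] @ Ls.T).T
    return ParameterState(
        Theta=Theta, sigma_x2=sigma_x2, eta=eta, Lambda=Lambda, U=U, Bc=Bc,
        xi=xi, Sigma_y=np.atleast_2d(Sigma_y), nu2=nu2, nu_aux=float(nu_aux),
        phi=phi, delta=delta, lambda_phi=lambda_phi, lambda_delta=lambda_delta,
        psi=psi, zeta=zeta, kappa=kappa, X=None, Y=None,
    )


def draw_data(state, data, rng):
    """Data from the likelihood given the current parameters."""
    n, p = data.n, data.p
    X = state.eta @ state.Theta.T + rng.standard_normal((n, p)) * np.sqrt(
        state.sigma_x2
    )
    Ut = state.U[:, :, data.t_idx]
    W = np.einsum("hkr,rk->rh", Ut, state.eta[data.subj])
    mean = W @ state.Lambda.T + data.Z @ state.Bc.T + state.xi[data.subj]
    Ls = np.linalg.cholesky(state.Sigma_y)
    Y = mean + rng.standard_normal((data.N, data.q)) @ Ls.T
    return X, Y


def gibbs_sweep(state, data, config, rng):
    state.X, state.Y = draw_data(state, data, rng)
    update_eta(state, data, config, rng)
    update_factor_block(state, data, config, rng)
    update_gp_block(state, data, config, rng)
    update_covariate_block(state, data, config, rng)
    update_subject_block(state, data, config, rng)
    update_kappa(state, data, config, rng)


STAT_NAMES = [
    "theta_00", "mean_abs_theta", "log_sigma_x2_0", "eta_00",
    "mean_log_diag_Sigma_y", "corr_Sigma_y", "log_nu2", "tanh_Bc_00",
    "mean_abs_Lambda", "u_000", "kappa",
]


def stats_vector(state):
    Sy = state.Sigma_y
    corr = Sy[0, 1] / np.sqrt(Sy[0, 0] * Sy[1, 1])
    return np.array(
        [
            state.Theta[0, 0],
            np.abs(state.Theta).mean(),
            np.log(state.sigma_x2[0]),
            state.eta[0, 0],
            np.log(np.diag(Sy)).mean(),
            corr,
            np.log(state.nu2),
            np.tanh(state.Bc[0, 0]),
            np.abs(state.Lambda).mean(),
            state.U[0, 0, 0],
            state.kappa,
        ]
    )


def batch_means_se(x, n_batches=25):
    """Standard error of the mean of an autocorrelated sequence.

    Few, long batches: short batches underestimate the error badly for
    slowly mixing statistics.
    """
    m = len(x) // n_batches
    means = x[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(n_batches)


def geweke_z_scores(n_forward=20_000, n_gibbs=100_000, seed=0):
    """z-scores comparing forward and successive-conditional moments."""
    config = tiny_config()
    rng = np.random.default_rng(seed)
    n, T, L = DIMS["n"], DIMS["T"], DIMS["L"]
    times = np.arange(1.0, T + 1)
    subj = np.repeat(np.arange(n), T)
    t_idx = np.tile(np.arange(T), n)
    Z = rng.standard_normal((n * T, L))

    from bmfr.data import CovariateTable, ExposurePanel, LongitudinalOutcomes

    placeholder_X = np.zeros((n, DIMS["p"]))
    placeholder_Y = np.zeros((n * T, DIMS["q"]))
    data = FitData(
        ExposurePanel(placeholder_X),
        LongitudinalOutcomes(placeholder_Y, subj, t_idx, times),
        CovariateTable(Z),
    )

    fwd = np.empty((n_forward, len(STAT_NAMES)))
    for s in range(n_forward):
        fwd[s] = stats_vector(prior_state(config, rng, Z, times))

    state = prior_state(config, rng, Z, times)
    gib = np.empty((n_gibbs, len(STAT_NAMES)))
    for s in range(n_gibbs):
        gibbs_sweep(state, data, config, rng)
        gib[s] = stats_vector(state)

    z = np.empty(len(STAT_NAMES))
    for i in range(len(STAT_NAMES)):
        se_f = fwd[:, i].std(ddof=1) / np.sqrt(n_forward)
        se_g = batch_means_se(gib[:, i])
        z[i] = (fwd[:, i].mean() - gib[:, i].mean()) / np.hypot(se_f, se_g)
    return dict(zip(STAT_NAMES, z))
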