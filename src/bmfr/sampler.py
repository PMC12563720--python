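"""Gibbs sampler for the Bayesian multivariate factor regression.

Every block has a conjugate Gaussian / gamma / inverse-Wishart full
conditional derived from the likelihood

    x_i  ~ N_p(Theta eta_i, Sigma_X)
    y_it ~ N_q(Lambda U(t) eta_i + B_c z_it + xi_i, Sigma_Y)

together with the priors: standard-normal factors, multiplicative-gamma-
process loadings (for both Theta and Lambda), Gaussian-process rows of U,
horseshoe-type global-local shrinkage on B_c, half-Cauchy on the
between-subject scale nu (via inverse-gamma parameter expansion), and an
inverse-Wishart on Sigma_Y. Censored exposures and missing outcomes are
re-imputed at the top of every sweep so each block conditions on complete
data. The length scale kappa is updated by exact discrete Gibbs on a grid,
or by an adaptive log-scale random walk when a continuous range is
configured.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import cho_solve, solve_triangular

from .config import ModelConfig
from .core import assemble_B, gp_kernel_matrix, jittered_cholesky, mgp_tau
from .data import CovariateTable, ExposurePanel, LongitudinalOutcomes
from .state import ParameterState, PosteriorDraws

logger = logging.getLogger(__name__)

__all__ = [
    "FitData",
    "ChainController",
    "run_chain",
    "initialize_state",
    "update_eta",
    "update_factor_block",
    "update_gp_block",
    "update_covariate_block",
    "update_subject_block",
    "update_kappa",
    "impute_censored_exposures",
    "impute_missing_outcomes",
]


# ---------------------------------------------------------------------------
# data plumbing


class FitData:
    """Precomputed index structures shared by all update blocks."""

    def __init__(
        self,
        exposures: ExposurePanel,
        outcomes: LongitudinalOutcomes,
        covariates: CovariateTable | None = None,
    ):
        self.exposures = exposures
        self.outcomes = outcomes
        self.X0 = exposures.values.astype(float).copy()
        self.cens = exposures.censored
        self.lod = exposures.lod
        self.n, self.p = self.X0.shape
        if outcomes.n_subjects > self.n:
            raise ValueError("outcome records reference unknown subjects")
        self.Y0 = np.nan_to_num(outcomes.y.astype(float))
        self.miss = outcomes.missing
        self.subj = outcomes.subject_index
        self.t_idx = outcomes.t_index
        self.times = outcomes.grid.astype(float)
        self.N, self.q = self.Y0.shape
        self.T = len(self.times)
        self.Z = covariates.z if covariates is not None else None
        self.L = 0 if self.Z is None else self.Z.shape[1]
        self.Ti = np.bincount(self.subj, minlength=self.n)  # visits per subject
        self.miss_any = self.miss.any()
        if self.miss_any:
            self.miss_rows = np.nonzero(self.miss.any(axis=1))[0]
            patterns: dict[tuple, list[int]] = {}
            for r in self.miss_rows:
                patterns.setdefault(tuple(self.miss[r]), []).append(r)
            self.miss_patterns = [
                (np.array(k, dtype=bool), np.array(v)) for k, v in patterns.items()
            ]
        else:
            self.miss_rows = np.empty(0, dtype=int)
            self.miss_patterns = []


@dataclass
class ChainController:
    """Iteration bookkeeping: seed, counters, storage policy, kappa tallies."""

    seed: int
    n_iter: int
    n_burn: int
    thin: int
    log_every: int = 500
    iteration: int = 0
    kappa_proposals: int = 0
    kappa_accepts: int = 0
    kappa_step: float = 0.5  # log-scale RW step (continuous mode)

    def store_this(self) -> bool:
        i = self.iteration
        return i >= self.n_burn and (i - self.n_burn) % self.thin == 0

    @property
    def kappa_acceptance(self) -> float:
        return self.kappa_accepts / max(self.kappa_proposals, 1)


# ---------------------------------------------------------------------------
# helpers


def _sample_mvn_prec(Q: np.ndarray, b: np.ndarray, rng: np.random.Generator):
    """Draw from N(Q^-1 b, Q^-1) via Cholesky of the precision Q."""
    L = jittered_cholesky(Q)
    mean = cho_solve((L, True), b)
    z = rng.standard_normal(b.shape[0])
    return mean + solve_triangular(L.T, z, lower=False)

def _invgamma(rng: np.random.Generator, shape: float, rate, size=None):
    return 1.0 / rng.gamma(shape, 1.0 / np.asarray(rate), size=size)


def _record_means(state: ParameterState, data: FitData, *, skip=()) -> np.ndarray:
    """Per-record model mean, optionally leaving out components in ``skip``."""
    mean = np.zeros((data.N, data.q))
    if "B" not in skip:
        Ut = state.U[:, :, data.t_idx]  # (H, K, N)
        W = np.einsum("hkn,nk->nh", Ut, state.eta[data.subj])
        mean += W @ state.Lambda.T
    if "Z" not in skip and data.Z is not None and state.Bc is not None:
        mean += data.Z @ state.Bc.T
    if "xi" not in skip:
        mean += state.xi[data.subj]
    return mean


# ---------------------------------------------------------------------------
# imputation blocks


def impute_censored_exposures(
    state: ParameterState, data: FitData, rng: np.random.Generator
) -> None:
    """Redraw below-LOD exposure entries from upper-truncated normals.

    Each censored cell (i, j) is drawn from N(theta_j' eta_i, sigma_j^2)
    truncated above at the metabolite's log-LOD; scipy's inverse-CDF
    truncated-normal sampler handles deep-tail truncation without
    rejection loops.
    """
    if not data.cens.any():
        return
    rows, cols = np.nonzero(data.cens)
    mu = np.einsum("nk,nk->n", state.eta[rows], state.Theta[cols])
    sd = np.sqrt(state.sigma_x2[cols])
    beta = (data.lod[cols] - mu) / sd
    draws = stats.truncnorm.rvs(-np.inf, beta, loc=mu, scale=sd, random_state=rng)
    state.X[rows, cols] = draws


def impute_missing_outcomes(
    state: ParameterState, data: FitData, rng: np.random.Generator
) -> None:
    """Redraw missing outcome coordinates from their conditional Gaussian.

    Given the full model mean mu (factor, covariate and random-intercept
    parts) the missing block of each record is Gaussian with the usual
    Schur-complement mean and covariance against the observed block.
    """
    if not data.miss_any:
        return
    mu_all = _record_means(state, data)
    Sig = state.Sigma_y
    for mask, rows in data.miss_patterns:
        obs = ~mask
        mu = mu_all[rows]
        if not obs.any():  # excluded at load; defensive
            continue
        S_oo = Sig[np.ix_(obs, obs)]
        S_mo = Sig[np.ix_(mask, obs)]
        S_mm = Sig[np.ix_(mask, mask)]
        L_oo = jittered_cholesky(S_oo)
        G = cho_solve((L_oo, True), S_mo.T).T  # S_mo S_oo^-1
        resid = state.Y[np.ix_(rows, obs)] - mu[:, obs]
        cond_mean = mu[:, mask] + resid @ G.T
        V = S_mm - G @ S_mo.T
        Lv = jittered_cholesky(V)
        z = rng.standard_normal((len(rows), int(mask.sum())))
        state.Y[np.ix_(rows, mask)] = cond_mean + z @ Lv.T


# ---------------------------------------------------------------------------
# Gaussian blocks


def update_eta(
    state: ParameterState, data: FitData, config: ModelConfig,
    rng: np.random.Generator,
) -> None:
    """Draw factor scores from their exact multivariate-normal conditional.

    Precision: I_K + Theta' Sigma_X^-1 Theta + sum_t B(t)' Sigma_Y^-1 B(t)
    over the subject's visits; the mean combines exposure and outcome
    evidence. Batched over subjects with a vectorized Cholesky.
    """
    K = config.K
    ThS = state.Theta.T / state.sigma_x2  # (K, p)
    Q_shared = np.eye(K) + ThS @ state.Theta
    rhs = state.X @ ThS.T  # (n, K)
    Q = np.broadcast_to(Q_shared, (data.n, K, K)).copy()
    if data.N:
        B = assemble_B(state.Lambda, state.U)  # (q, K, T)
        Sy_inv = _pd_inverse(state.Sigma_y)
        BtS = np.einsum("qkt,qm->tkm", B, Sy_inv)  # B(t)' Sigma_Y^-1, (T,K,q)
        M = np.einsum("tkq,qjt->tkj", BtS, B)  # M_t = B(t)' Sy^-1 B(t)
        resid = state.Y - _record_means(state, data, skip=("B",))
        np.add.at(Q, data.subj, M[data.t_idx])
        contrib = np.einsum("rkq,rq->rk", BtS[data.t_idx], resid)
        np.add.at(rhs, data.subj, contrib)
    Lc = np.linalg.cholesky(Q)
    mean = np.linalg.solve(Q, rhs[..., None])[..., 0]
    z = rng.standard_normal((data.n, K))
    # solve L^T w = z for each subject
    w = np.linalg.solve(np.swapaxes(Lc, 1, 2), z[..., None])[..., 0]
    state.eta = mean + w


def _pd_inverse(mat: np.ndarray) -> np.ndarray:
    L = jittered_cholesky(mat)
    return cho_solve((L, True), np.eye(mat.shape[0]))


def update_factor_block(
    state: ParameterState, data: FitData, config: ModelConfig,
    rng: np.random.Generator,
) -> None:
    """Draw Theta rows, idiosyncratic variances and their MGP locals."""
    n, p, K = data.n, data.p, config.K
    eta = state.eta
    EtE = eta.T @ eta
    tau = mgp_tau(state.delta)
    for j in range(p):
        Dj = state.phi[j] * tau
        Q = np.diag(Dj) + EtE / state.sigma_x2[j]
        b = eta.T @ state.X[:, j] / state.sigma_x2[j]
        state.Theta[j] = _sample_mvn_prec(Q, b, rng)
    resid = state.X - eta @ state.Theta.T
    rate = config.sigma_x_rate + 0.5 * np.einsum("nj,nj->j", resid, resid)
    state.sigma_x2 = _invgamma(rng, config.sigma_x_shape + 0.5 * n, rate)
    v = config.mgp_v
    phi_rate = 0.5 * (v + tau[None, :] * state.Theta**2)
    state.phi = rng.gamma(0.5 * (v + 1.0), 1.0 / phi_rate)
    _update_mgp_delta(
        state.delta, state.phi, state.Theta, config.mgp_a1, config.mgp_a2, rng
    )


def _update_mgp_delta(delta, phi, loadings, a1, a2, rng) -> None:
    """Sequential gamma updates of the MGP increments (in place).

    The conditional of delta_l aggregates the weighted squared loadings of
    every column h >= l, with the l-th increment factored out of tau_h.
    """
    p, K = loadings.shape
    s = np.einsum("jk,jk->k", phi, loadings**2)  # sum_j phi_jk theta_jk^2
    for l in range(K):
        tau = np.cumprod(delta)
        tau_minus = tau[l:] / delta[l]
        shape = (a1 if l == 0 else a2) + 0.5 * p * (K - l)
        rate = 1.0 + 0.5 * np.sum(tau_minus * s[l:])
        delta[l] = rng.gamma(shape, 1.0 / rate)


def update_gp_block(
    state: ParameterState, data: FitData, config: ModelConfig,
    rng: np.random.Generator,
) -> None:
    """Draw the GP basis functions U row by row, then Lambda and its MGP.

    Each T-vector u_hk has prior N(0, C) and a diagonal likelihood
    precision (every outcome record touches exactly one grid time), so its
    conditional is a T-dimensional Gaussian. Lambda is drawn jointly as
    vec(Lambda) (dimension qH) because a non-diagonal Sigma_Y couples its
    rows.
    """
    H, K, T, q = config.H, config.K, data.T, data.q
    C = gp_kernel_matrix(data.times, state.kappa, convention=config.kappa_convention)
    Lc = jittered_cholesky(C)
    C_inv = cho_solve((Lc, True), np.eye(T))
    Sy_inv = _pd_inverse(state.Sigma_y)
    eta_rec = state.eta[data.subj]  # (N, K)
    if data.N == 0:
        # prior draws
        for h in range(H):
            for k in range(K):
                state.U[h, k] = Lc @ rng.standard_normal(T)
        _draw_lambda_prior(state, config, rng)
        return
    Ut = state.U[:, :, data.t_idx]  # (H, K, N)
    W = np.einsum("hkn,nk->nh", Ut, eta_rec)
    base = np.zeros((data.N, q))
    if data.Z is not None and state.Bc is not None:
        base += data.Z @ state.Bc.T
    base += state.xi[data.subj]
    Rfull = state.Y - base - W @ state.Lambda.T
    for h in range(H):
        lam_h = state.Lambda[:, h]
        g = Sy_inv @ lam_h
        c_h = float(lam_h @ g)
        for k in range(K):
            ek = eta_rec[:, k]
            u_cur = state.U[h, k]
            contrib = ek * u_cur[data.t_idx]
            R_ex = Rfull + np.outer(contrib, lam_h)
            d = c_h * np.bincount(data.t_idx, weights=ek**2, minlength=T)
            b = np.bincount(data.t_idx, weights=ek * (R_ex @ g), minlength=T)
            Q = C_inv + np.diag(d)
            u_new = _sample_mvn_prec(Q, b, rng)
            state.U[h, k] = u_new
            Rfull = R_ex - np.outer(ek * u_new[data.t_idx], lam_h)
    # --- Lambda | rest: joint draw of vec(Lambda), entries lambda_jh at h*q+j
    Ut = state.U[:, :, data.t_idx]
    W = np.einsum("hkn,nk->nh", Ut, eta_rec)  # (N, H)
    Rres = state.Y - base  # residual without the B part
    S_w = W.T @ W
    P = np.kron(S_w, Sy_inv)
    lam_tau = mgp_tau(state.lambda_delta)
    prior_prec = (state.lambda_phi * lam_tau[None, :]).T.ravel()  # h*q+j order
    P[np.diag_indices_from(P)] += prior_prec
    bvec = (W.T @ (Rres @ Sy_inv)).ravel()
    v = _sample_mvn_prec(P, bvec, rng)
    state.Lambda = v.reshape(H, q).T
    # --- MGP locals for Lambda
    mv = config.mgp_v
    phi_rate = 0.5 * (mv + lam_tau[None, :] * state.Lambda**2)
    state.lambda_phi = rng.gamma(0.5 * (mv + 1.0), 1.0 / phi_rate)
    _update_mgp_delta(
        state.lambda_delta, state.lambda_phi, state.Lambda,
        config.mgp_a1, config.mgp_a2, rng,
    )


def _draw_lambda_prior(state, config, rng) -> None:
    lam_tau = mgp_tau(state.lambda_delta)
    sd = 1.0 / np.sqrt(state.lambda_phi * lam_tau[None, :])
    state.Lambda = rng.standard_normal(state.Lambda.shape) * sd


def update_covariate_block(
    state: ParameterState, data: FitData, config: ModelConfig,
    rng: np.random.Generator,
) -> None:
    """Draw B_c from its matrix-normal conditional, then the shrinkage locals.

    The prior MN(0, Sigma_Y, Psi) shares its row covariance with the noise,
    so the posterior is matrix-normal with column precision Z'Z + Psi^-1.
    psi_l has a generalized-inverse-Gaussian conditional; zeta_l a gamma.
    """
    if data.Z is None or state.Bc is None:
        return
    L = data.L
    q = data.q
    Rc = state.Y - _record_means(state, data, skip=("Z",))
    Q = data.Z.T @ data.Z + np.diag(1.0 / state.psi)
    Lq = jittered_cholesky(Q)
    M = cho_solve((Lq, True), data.Z.T @ Rc)  # (L, q)
    G = rng.standard_normal((L, q))
    A = solve_triangular(Lq.T, G, lower=False)  # A A' = Q^-1 row-cov factor
    Ls = jittered_cholesky(state.Sigma_y)
    state.Bc = (M + A @ Ls.T).T  # (q, L)
    # psi_l | b_l ~ GIG(u - q/2, b_l' Sy^-1 b_l, 2 zeta_l)
    Sy_inv = _pd_inverse(state.Sigma_y)
    chi = np.einsum("ql,qm,ml->l", state.Bc, Sy_inv, state.Bc)
    chi = np.maximum(chi, 1e-12)
    lam = config.hs_u - 0.5 * q
    psi_par = 2.0 * state.zeta
    b_gig = np.sqrt(chi * psi_par)
    draws = stats.geninvgauss.rvs(lam, b_gig, random_state=rng)
    state.psi = np.maximum(np.sqrt(chi / psi_par) * draws, 1e-12)
    r = config.hs_r
    state.zeta = rng.gamma(config.hs_u + config.hs_v, 1.0 / (r + state.psi))


def update_subject_block(
    state: ParameterState, data: FitData, config: ModelConfig,
    rng: np.random.Generator,
) -> None:
    """Draw random intercepts, the between-subject scale and Sigma_Y.

    xi_i | rest is Gaussian with covariance Sigma_Y / (T_i + 1/nu^2); nu^2
    follows the inverse-gamma parameter expansion of the half-Cauchy; the
    inverse-Wishart for Sigma_Y aggregates outcome residuals, the scaled
    intercepts and (because its prior row covariance is Sigma_Y) the
    covariate coefficients.
    """
    n, q = data.n, data.q
    resid = state.Y - _record_means(state, data, skip=("xi",))
    S = np.zeros((n, q))
    np.add.at(S, data.subj, resid)
    denom = data.Ti + 1.0 / state.nu2  # (n,)
    mean = S / denom[:, None]
    Ls = jittered_cholesky(state.Sigma_y)
    z = rng.standard_normal((n, q))
    state.xi = mean + (z @ Ls.T) / np.sqrt(denom)[:, None]
    # nu^2 (parameter expansion for half-Cauchy(nu_scale) on nu)
    Sy_inv = _pd_inverse(state.Sigma_y)
    quad = float(np.einsum("nq,qm,nm->", state.xi, Sy_inv, state.xi))
    state.nu2 = float(
        _invgamma(rng, 0.5 * (n * q + 1.0), 1.0 / state.nu_aux + 0.5 * quad)
    )
    state.nu_aux = float(
        _invgamma(rng, 1.0, 1.0 / config.nu_scale**2 + 1.0 / state.nu2)
    )
    # Sigma_Y
    eps = resid - state.xi[data.subj]
    scale = np.asarray(config.iw_S0, dtype=float).copy()
    scale += eps.T @ eps
    scale += (state.xi.T @ state.xi) / state.nu2
    df = config.iw_s0 + data.N + n
    if state.Bc is not None:
        scale += (state.Bc / state.psi[None, :]) @ state.Bc.T
        df += data.L
    scale = 0.5 * (scale + scale.T)
    state.Sigma_y = stats.invwishart.rvs(df, scale, random_state=rng)
    if q == 1:
        state.Sigma_y = np.atleast_2d(state.Sigma_y)


def update_kappa(
    state: ParameterState, data: FitData, config: ModelConfig,
    rng: np.random.Generator, ctrl: ChainController | None = None,
) -> None:
    """Update the GP length scale.

    Grid mode: exact discrete Gibbs over the configured grid, with the
    conditional proportional to the GP prior density of all u_hk rows.
    Continuous mode: log-scale random-walk Metropolis with Robbins-Monro
    step adaptation targeting 0.44 acceptance (frozen after burn-in).
    """
    if config.kappa_is_fixed:
        return
    rows = state.U.reshape(-1, data.T)  # (H*K, T)

    def log_density(kap: float) -> float:
        C = gp_kernel_matrix(data.times, kap, convention=config.kappa_convention)
        Lc = jittered_cholesky(C)
        logdet = 2.0 * np.sum(np.log(np.diag(Lc)))
        sol = solve_triangular(Lc, rows.T, lower=True)
        quad = float(np.sum(sol**2))
        return -0.5 * (rows.shape[0] * logdet + quad)

    if getattr(config, "kappa_continuous", False):
        lo, hi = config.kappa
        step = ctrl.kappa_step if ctrl is not None else 0.5
        prop = float(np.exp(np.log(state.kappa) + step * rng.standard_normal()))
        if ctrl is not None:
            ctrl.kappa_proposals += 1
        if lo <= prop <= hi:
            # symmetric proposal on log scale; log-uniform correction for the
            # uniform prior on kappa is the log-Jacobian ratio
            logr = log_density(prop) - log_density(state.kappa)
            logr += np.log(prop) - np.log(state.kappa)
            accept = np.log(rng.uniform()) < logr
        else:
            accept = False
        if accept:
            state.kappa = prop
            if ctrl is not None:
                ctrl.kappa_accepts += 1
        if ctrl is not None and ctrl.iteration < ctrl.n_burn:
            rate = 1.0 / max(ctrl.kappa_proposals, 1) ** 0.6
            ctrl.kappa_step = float(
                np.exp(np.log(ctrl.kappa_step) + rate * ((1.0 if accept else 0.0) - 0.44))
            )
        return
    grid = np.asarray(config.kappa, dtype=float)
    logp = np.array([log_density(k) for k in grid])
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    idx = rng.choice(len(grid), p=prob)
    if ctrl is not None:
        ctrl.kappa_proposals += 1
        ctrl.kappa_accepts += 1  # discrete Gibbs always accepts
    state.kappa = float(grid[idx])


# ---------------------------------------------------------------------------
# initialization and the chain driver


def initialize_state(
    data: FitData, config: ModelConfig, rng: np.random.Generator
) -> ParameterState:
    """Data-informed starting point: SVD factors for X, zeros elsewhere."""
    n, p, q, K, H, T = data.n, data.p, data.q, config.K, config.H, data.T
    X = data.X0.copy()
    if data.cens.any():
        rows, cols = np.nonzero(data.cens)
        X[rows, cols] = data.lod[cols] - 0.8  # valid start below the bound
    Y = data.Y0.copy()
    Y[data.miss] = 0.0
    Uv, sv, Vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
    k_eff = min(K, len(sv))
    Theta = np.zeros((p, K))
    Theta[:, :k_eff] = Vt[:k_eff].T * sv[:k_eff] / np.sqrt(n)
    eta = np.zeros((n, K))
    eta[:, :k_eff] = Uv[:, :k_eff] * np.sqrt(n)
    resid_var = np.maximum(np.var(X - eta @ Theta.T, axis=0), 0.05)
    kappa0 = (
        float(config.kappa)
        if config.kappa_is_fixed
        else float(np.median(np.asarray(config.kappa)))
    )
    Sigma_y0 = np.cov(Y, rowvar=False) if data.N > q else np.eye(q)
    Sigma_y0 = np.atleast_2d(Sigma_y0) + 1e-6 * np.eye(q)
    return ParameterState(
        Theta=Theta,
        sigma_x2=resid_var,
        eta=eta,
        Lambda=0.1 * rng.standard_normal((q, H)),
        U=np.zeros((H, K, T)),
        Bc=np.zeros((q, data.L)) if data.L else None,
        xi=np.zeros((n, q)),
        Sigma_y=Sigma_y0,
        nu2=1.0,
        nu_aux=1.0,
        phi=np.ones((p, K)),
        delta=np.ones(K),
        lambda_phi=np.ones((q, H)),
        lambda_delta=np.ones(H),
        psi=np.ones(data.L) if data.L else None,
        zeta=np.ones(data.L) if data.L else None,
        kappa=kappa0,
        X=X,
        Y=Y,
    )


def _resolve_config(data: FitData, config: ModelConfig) -> ModelConfig:
    """Fill data-dependent defaults (IW scale, horseshoe global rate)."""
    updates = {}
    if config.iw_S0 is None:
        S0 = np.cov(data.Y0, rowvar=False) if data.N > data.q else np.eye(data.q)
        updates["iw_S0"] = np.atleast_2d(S0)
    if config.hs_r is None and data.L:
        n = max(data.n, 3)
        updates["hs_r"] = 1.0 / (config.K * n * np.log(n))
    elif config.hs_r is None:
        updates["hs_r"] = 1.0
    if config.iw_s0 < data.q:
        raise ValueError(
            f"iw_s0={config.iw_s0} below the outcome dimension q={data.q}; "
            "the inverse-Wishart prior would be improper"
        )
    return config.replace(**updates) if updates else config


def run_chain(
    exposures: ExposurePanel,
    outcomes: LongitudinalOutcomes,
    covariates: CovariateTable | None,
    config: ModelConfig,
    *,
    log_every: int = 1000,
) -> PosteriorDraws:
    """Run the full Gibbs sampler and return stored posterior draws.

    Update order per sweep: imputations, eta, factor block, GP block,
    covariate block, subject block, kappa — imputations first so every
    block conditions on complete data. Deterministic under a fixed seed.
    """
    if config.seed is None:
        raise ValueError("config.seed is required for a reproducible chain")
    data = FitData(exposures, outcomes, covariates)
    config = _resolve_config(data, config)
    rng = np.random.default_rng(config.seed)
    state = initialize_state(data, config, rng)
    ctrl = ChainController(
        seed=config.seed, n_iter=config.n_iter, n_burn=config.n_burn,
        thin=config.thin, log_every=log_every,
    )
    stored: list[ParameterState] = []
    y_missing_trace: list[np.ndarray] = []
    t0 = time.time()
    for it in range(config.n_iter):
        ctrl.iteration = it
        try:
            impute_censored_exposures(state, data, rng)
            impute_missing_outcomes(state, data, rng)
            update_eta(state, data, config, rng)
            update_factor_block(state, data, config, rng)
            update_gp_block(state, data, config, rng)
            update_covariate_block(state, data, config, rng)
            update_subject_block(state, data, config, rng)
            update_kappa(state, data, config, rng, ctrl)
        except Exception as exc:
            raise RuntimeError(f"sampler failed at iteration {it}: {exc}") from exc
        if ctrl.store_this():
            snap = state.copy()
            for name in ("Theta", "Lambda", "U", "Sigma_y", "eta"):
                if not np.all(np.isfinite(getattr(snap, name))):
                    raise RuntimeError(f"non-finite {name} draw at iteration {it}")
            if data.miss_any:
                y_missing_trace.append(state.Y[data.miss].copy())
            snap.Y = None  # keep storage small; missing cells traced above
            stored.append(snap)
        if log_every and (it + 1) % log_every == 0:
            logger.info("iteration %d/%d", it + 1, config.n_iter)
    meta = {
        "seed": config.seed,
        "config": config.to_dict(),
        "kappa_acceptance": ctrl.kappa_acceptance,
        "wall_clock_s": time.time() - t0,
        "n_stored": len(stored),
    }
    draws = PosteriorDraws.from_states(stored, meta)
    if y_missing_trace:
        draws.draws["Y_missing"] = np.stack(y_missing_trace)
    if not data.cens.any():
        draws.draws.pop("X_imputed", None)
    return draws
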