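"""Deterministic model mathematics.

The regression model ties a latent-factor representation of a correlated
exposure mixture to multivariate longitudinal outcomes:

* exposures      ``x_i ~ N_p(Theta eta_i, Sigma_X)`` with ``eta_i ~ N_K(0, I)``,
* outcomes       ``y_it ~ N_q(B(t) eta_i + B_c z_it + xi_i, Sigma_Y)``,
* effect surface ``B(t) = Lambda U(t)`` with Gaussian-process rows of ``U``.

Everything in this module is pure linear algebra shared by the Gibbs sampler,
the post-processing code and the prediction path.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "gp_kernel_matrix",
    "jittered_cholesky",
    "mgp_tau",
    "assemble_B",
    "factor_score_map",
    "induced_exposure_effects",
    "predict_outcomes",
]


def gp_kernel_matrix(
    times: np.ndarray,
    kappa: float,
    *,
    convention: str = "divisor",
) -> np.ndarray:
    """Squared-exponential kernel matrix on a grid of visit ages.

    Parameters
    ----------
    times
        Strictly increasing grid of ages (length ``T``).
    kappa
        Positive length scale. Under the default ``"divisor"`` convention the
        entry for lag ``d`` is ``exp(-0.5 * (d / kappa)**2)``; the
        ``"multiplier"`` convention uses ``exp(-0.5 * (d * kappa)**2)``.
    convention
        ``"divisor"`` (default) or ``"multiplier"``.

    Returns
    -------
    ndarray of shape (T, T)
        Unit-diagonal, symmetric, positive-semidefinite kernel matrix. The
        amplitude is fixed to 1; effect magnitude is carried by the basis
        loadings.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-d array")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if not np.isfinite(kappa) or kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa!r}")
    lags = times[:, None] - times[None, :]
    if convention == "divisor":
        z = lags / kappa
    elif convention == "multiplier":
        z = lags * kappa
    else:
        raise ValueError(f"unknown kernel convention {convention!r}")
    return np.exp(-0.5 * z**2)


def jittered_cholesky(mat: np.ndarray, *, max_tries: int = 8) -> np.ndarray:
    """Lower Cholesky factor with escalating diagonal jitter.

    Starts at ``1e-10 * mean(diag)`` and multiplies by 10 on each failure.
    Raises :class:`numpy.linalg.LinAlgError` if the matrix is still not
    positive definite after ``max_tries`` escalations.
    """
    mat = np.asarray(mat, dtype=float)
    scale = float(np.mean(np.diag(mat)))
    if scale <= 0:
        scale = 1.0
    jitter = 0.0
    for attempt in range(max_tries):
        try:
            return np.linalg.cholesky(mat + jitter * np.eye(mat.shape[0]))
        except np.linalg.LinAlgError:
            jitter = scale * 10.0 ** (-10 + attempt)
    raise np.linalg.LinAlgError(
        f"Cholesky failed after jitter escalation up to {jitter:.2e}"
    )


def mgp_tau(delta: np.ndarray) -> np.ndarray:
    """Column precisions of the multiplicative gamma process.

    ``tau_h = prod_{l<=h} delta_l``; with increments >= 1 the precisions are
    nondecreasing, shrinking later factor columns harder.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= 0) or not np.all(np.isfinite(delta)):
        raise ValueError("MGP increments must be positive and finite")
    return np.cumprod(delta)


def assemble_B(Lambda: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Assemble the time-varying coefficient array ``B(t) = Lambda U(t)``.

    Parameters
    ----------
    Lambda : (q, H) basis loadings
    U : (H, K, T) basis functions evaluated on the time grid

    Returns
    -------
    (q, K, T) array with ``B[:, :, t] = Lambda @ U[:, :, t]``.
    """
    Lambda = np.asarray(Lambda, dtype=float)
    U = np.asarray(U, dtype=float)
    if Lambda.ndim != 2 or U.ndim != 3 or Lambda.shape[1] != U.shape[0]:
        raise ValueError(
            f"shape mismatch: Lambda {Lambda.shape} vs U {U.shape} "
            "(need Lambda (q,H) and U (H,K,T))"
        )
    return np.einsum("qh,hkt->qkt", Lambda, U)


def factor_score_map(Theta: np.ndarray, sigma_x2: np.ndarray) -> np.ndarray:
    """Linear map ``A`` with ``E[eta | x] = A x`` under the factor model.

    ``A = (Theta' Sigma_X^-1 Theta + I_K)^-1 Theta' Sigma_X^-1``; the identity
    ridge comes from the standard-normal factor prior, so the normal-equations
    matrix is always invertible.
    """
    Theta = np.asarray(Theta, dtype=float)
    sigma_x2 = np.asarray(sigma_x2, dtype=float)
    if np.any(sigma_x2 <= 0):
        raise ValueError("idiosyncratic variances must be positive")
    K = Theta.shape[1]
    Ts = Theta.T / sigma_x2  # Theta' Sigma_X^-1, shape (K, p)
    Q = Ts @ Theta + np.eye(K)
    return np.linalg.solve(Q, Ts)


def induced_exposure_effects(
    B: np.ndarray, Theta: np.ndarray, sigma_x2: np.ndarray
) -> np.ndarray:
    """Back-transform factor effects to per-exposure effects.

    The effect of a one-unit increase in exposure ``j`` on outcome ``m`` at
    grid time ``t`` is ``(B(t) A)[m, j]`` where ``A`` maps exposures to
    conditional factor means, ``E[eta | x] = A x``.

    Parameters
    ----------
    B : (q, K, T) factor-effect array
    Theta : (p, K) loadings
    sigma_x2 : (p,) idiosyncratic variances

    Returns
    -------
    (q, p, T) array of induced per-exposure effects.
    """
    A = factor_score_map(Theta, sigma_x2)  # (K, p)
    return np.einsum("qkt,kp->qpt", np.asarray(B, dtype=float), A)


def predict_outcomes(
    X_new: np.ndarray,
    B: np.ndarray,
    Theta: np.ndarray,
    sigma_x2: np.ndarray,
    Bc: np.ndarray | None = None,
    Z_new: np.ndarray | None = None,
) -> np.ndarray:
    """Mean outcome trajectories for new subjects from one parameter set.

    New subjects' factor scores are plugged in at their conditional mean
    ``eta_hat = A x`` and their (unseen) random intercepts at zero, so the
    prediction is ``B(t) eta_hat + B_c z``.

    Parameters
    ----------
    X_new : (m, p) preprocessed exposures (same centering/scaling as training)
    B : (q, K, T) coefficient array
    Theta, sigma_x2 : factor-model parameters defining the score map
    Bc : (q, L) covariate coefficients, optional
    Z_new : (m, T, L) or (m, L) covariates, required when ``Bc`` is given

    Returns
    -------
    (m, T, q) predicted mean outcomes on the (centered) model scale.
    """
    X_new = np.asarray(X_new, dtype=float)
    A = factor_score_map(Theta, sigma_x2)
    eta_hat = X_new @ A.T  # (m, K)
    pred = np.einsum("mk,qkt->mtq", eta_hat, np.asarray(B, dtype=float))
    if Bc is not None:
        if Z_new is None:
            raise ValueError("Z_new required when covariate coefficients are given")
        Z_new = np.asarray(Z_new, dtype=float)
        if Z_new.ndim == 2:  # baseline-only covariates, constant over time
            pred = pred + (Z_new @ np.asarray(Bc).T)[:, None, :]
        else:
            pred = pred + np.einsum("mtl,ql->mtq", Z_new, np.asarray(Bc))
    return pred
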