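"""Model configuration: prior hyperparameters, dimensions and chain settings."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import optimize, stats

__all__ = ["ModelConfig", "solve_sigma_x_rate"]


def solve_sigma_x_rate(shape: float = 2.0, prob: float = 0.99) -> float:
    """Inverse-gamma rate such that P(sigma^2 < 1) = ``prob`` at fixed shape.

    Exposures are standardized to unit variance, so the idiosyncratic noise
    variance of each one should be below 1 with high prior probability; the
    shape is pinned at a canonical weakly-informative value and the rate is
    solved numerically from that single probability constraint.
    """
    f = lambda b: stats.invgamma.cdf(1.0, shape, scale=b) - prob
    return float(optimize.brentq(f, 1e-8, 50.0))


@dataclass
class ModelConfig:
    """Hyperparameters and chain settings for the factor regression.

    Attributes
    ----------
    K, H
        Number of latent factors and of time basis functions (``H <= K``).
    mgp_a1, mgp_a2
        Gamma shapes of the multiplicative gamma process increments
        (first and subsequent columns).
    mgp_v
        Shape of the local Gamma(v/2, v/2) precisions on loadings.
    sigma_x_shape, sigma_x_rate
        Inverse-gamma prior on idiosyncratic exposure variances. When
        ``sigma_x_rate`` is None it is solved so that P(sigma^2 < 1) = 0.99.
    iw_s0, iw_S0
        Inverse-Wishart degrees of freedom and scale for the outcome residual
        covariance. ``iw_S0=None`` means "use the sample covariance of the
        outcomes", resolved at fit time.
    nu_scale
        Scale of the half-Cauchy prior on the between-subject standard
        deviation ratio ``nu``.
    hs_u, hs_v, hs_r
        Shrinkage-prior shapes for covariate coefficients (u = v = 1/2 gives
        the horseshoe) and the global rate; ``hs_r=None`` resolves to
        ``1 / (K * n * ln n)`` at fit time.
    kappa
        Gaussian-process length scale: a positive float (fixed) or a sequence
        of grid values with a uniform prior, sampled by discrete Gibbs.
    kappa_convention
        "divisor" (default) or "multiplier"; see
        :func:`bmfr.core.gp_kernel_matrix`.
    n_iter, n_burn, thin, seed
        Chain length, burn-in, thinning and the mandatory RNG seed.
    """

    K: int = 3
    H: int = 2
    mgp_a1: float = 2.1
    mgp_a2: float = 3.1
    mgp_v: float = 3.0
    sigma_x_shape: float = 2.0
    sigma_x_rate: float | None = None
    iw_s0: float = 6.0
    iw_S0: np.ndarray | None = None
    nu_scale: float = 25.0
    hs_u: float = 0.5
    hs_v: float = 0.5
    hs_r: float | None = None
    kappa: float | tuple[float, ...] = 6.0
    kappa_convention: str = "divisor"
    kappa_continuous: bool = False
    n_iter: int = 10_000
    n_burn: int = 5_000
    thin: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.H > self.K:
            raise ValueError(f"H={self.H} must not exceed K={self.K}")
        if self.K < 1 or self.H < 1:
            raise ValueError("K and H must be positive")
        for name in ("mgp_a1", "mgp_a2", "mgp_v", "sigma_x_shape", "iw_s0",
                     "nu_scale", "hs_u", "hs_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_x_rate is None:
            self.sigma_x_rate = solve_sigma_x_rate(self.sigma_x_shape)
        if self.sigma_x_rate <= 0:
            raise ValueError("sigma_x_rate must be positive")
        if self.hs_r is not None and self.hs_r <= 0:
            raise ValueError("hs_r must be positive")
        kappa = self.kappa
        if np.isscalar(kappa):
            if kappa <= 0:
                raise ValueError("kappa must be positive")
        else:
            kappa = tuple(float(k) for k in kappa)
            if len(kappa) == 0:
                raise ValueError("kappa grid must be non-empty")
            if any(k <= 0 for k in kappa):
                raise ValueError("kappa grid values must be positive")
            self.kappa = kappa
        if self.kappa_continuous:
            if np.isscalar(self.kappa) or len(self.kappa) != 2 or self.kappa[0] >= self.kappa[1]:
                raise ValueError(
                    "continuous kappa mode needs kappa=(lo, hi) with lo < hi"
                )
        if self.kappa_convention not in ("divisor", "multiplier"):
            raise ValueError(f"unknown kappa_convention {self.kappa_convention!r}")
        if not (0 <= self.n_burn < self.n_iter):
            raise ValueError("need 0 <= n_burn < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def kappa_is_fixed(self) -> bool:
        return np.isscalar(self.kappa)

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["iw_S0"], np.ndarray):
            d["iw_S0"] = d["iw_S0"].tolist()
        if not np.isscalar(d["kappa"]):
            d["kappa"] = list(d["kappa"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if d.get("iw_S0") is not None:
            d["iw_S0"] = np.asarray(d["iw_S0"], dtype=float)
        if isinstance(d.get("kappa"), list):
            d["kappa"] = tuple(d["kappa"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ModelConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
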