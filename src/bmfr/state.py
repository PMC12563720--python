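"""Sampler state containers and posterior-draw storage."""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

__all__ = ["ParameterState", "PosteriorDraws"]

# arrays stacked across stored draws
_DRAW_FIELDS = (
    "Theta", "sigma_x2", "eta", "Lambda", "U", "Bc", "xi", "Sigma_y",
    "nu2", "phi", "delta", "lambda_phi", "lambda_delta", "psi", "zeta",
    "kappa",
)


@dataclass
class ParameterState:
    """One full set of model unknowns (see module docstring of `core`).

    ``X`` and ``Y`` are the working copies of the data with censored exposure
    entries and missing outcome entries replaced by their current
    imputations.
    """

    Theta: np.ndarray  # (p, K)
    sigma_x2: np.ndarray  # (p,)
    eta: np.ndarray  # (n, K)
    Lambda: np.ndarray  # (q, H)
    U: np.ndarray  # (H, K, T)
    Bc: np.ndarray | None  # (q, L) or None
    xi: np.ndarray  # (n, q)
    Sigma_y: np.ndarray  # (q, q)
    nu2: float
    nu_aux: float  # parameter-expansion auxiliary for the half-Cauchy on nu
    phi: np.ndarray  # (p, K) MGP locals for Theta
    delta: np.ndarray  # (K,) MGP increments for Theta
    lambda_phi: np.ndarray  # (q, H) MGP locals for Lambda
    lambda_delta: np.ndarray  # (H,) MGP increments for Lambda
    psi: np.ndarray | None  # (L,) shrinkage local variances
    zeta: np.ndarray | None  # (L,) shrinkage local rates
    kappa: float
    X: np.ndarray | None = None  # (n, p) working exposures (imputed)
    Y: np.ndarray | None = None  # (N, q) working outcomes (imputed)

    def validate(self) -> None:
        if np.any(self.sigma_x2 <= 0):
            raise ValueError("sigma_x2 must be positive")
        if self.nu2 <= 0:
            raise ValueError("nu2 must be positive")
        if np.any(self.delta <= 0) or np.any(self.lambda_delta <= 0):
            raise ValueError("MGP increments must be positive")
        if not np.allclose(self.Sigma_y, self.Sigma_y.T):
            raise ValueError("Sigma_y must be symmetric")
        np.linalg.cholesky(self.Sigma_y)  # raises if not PD

    def copy(self) -> "ParameterState":
        kw = {}
        for f in fields(self):
            v = getattr(self, f.name)
            kw[f.name] = v.copy() if isinstance(v, np.ndarray) else v
        return ParameterState(**kw)


class PosteriorDraws:
    """Stacked post-burn-in, thinned parameter draws plus chain metadata.

    Each draw field is an array whose leading axis indexes stored draws;
    ``meta`` records the config, seed, kappa acceptance and timing.
    """

    def __init__(self, draws: dict[str, np.ndarray], meta: dict):
        self.draws = draws
        self.meta = dict(meta)

    def __len__(self) -> int:
        return self.draws["Theta"].shape[0]

    def __getattr__(self, name: str):
        try:
            return self.__dict__["draws"][name]
        except KeyError:
            raise AttributeError(name) from None

    def get(self, name: str) -> np.ndarray | None:
        return self.draws.get(name)

    def mean(self, name: str) -> np.ndarray:
        return self.draws[name].mean(axis=0)

    @classmethod
    def from_states(
        cls, states: list[ParameterState], meta: dict
    ) -> "PosteriorDraws":
        if not states:
            raise ValueError("no stored states")
        draws: dict[str, np.ndarray] = {}
        for name in _DRAW_FIELDS:
            first = getattr(states[0], name)
            if first is None:
                continue
            draws[name] = np.stack([np.asarray(getattr(s, name)) for s in states])
        # imputation traces: only the imputed cells, to keep storage small
        draws["X_imputed"] = np.stack([s.X for s in states]) if states[0].X is not None else None
        if draws["X_imputed"] is None:
            del draws["X_imputed"]
        return cls(draws, meta)

    # -- disk round trip --------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.draws.items():
            np.save(directory / f"{name}.npy", arr)
        (directory / "meta.json").write_text(json.dumps(self.meta, indent=2, default=str))

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorDraws":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        draws = {
            p.stem: np.load(p) for p in sorted(directory.glob("*.npy"))
        }
        return cls(draws, meta)
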