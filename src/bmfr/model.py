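"""Model and Results classes tying the sampler and post-processing together.

Typical use::

    from bmfr import BayesianFactorRegression, ModelConfig

    model = BayesianFactorRegression(exposures, outcomes, covariates,
                                     ModelConfig(K=3, H=2, seed=1))
    res = model.fit()
    print(res.summary())
    eff = res.effects(level=0.95)          # credible bands for B(t) and
                                           # induced per-exposure effects
    ranks = res.variable_importance()      # per-metabolite importance
    yhat = res.predict(X_new)              # (m, T, q) mean trajectories
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig
from .core import predict_outcomes
from .data import CovariateTable, ExposurePanel, LongitudinalOutcomes
from .postprocess import (
    EffectSummary,
    cv_grid_search,
    match_align,
    summarize_effects,
    variable_importance,
)
from .sampler import run_chain
from .state import PosteriorDraws

__all__ = ["BayesianFactorRegression", "FactorRegressionResults"]


class BayesianFactorRegression:
    """Bayesian multivariate factor regression with time-varying effects.

    Latent factors summarize a correlated exposure mixture; their effects on
    a vector of correlated longitudinal outcomes vary smoothly over a
    discrete age grid through a low-rank Gaussian-process expansion, with
    shrinkage-prior covariate adjustment, subject random intercepts, and
    in-sampler imputation of below-LOD exposures and missing outcomes.

    Parameters
    ----------
    exposures
        :class:`~bmfr.data.ExposurePanel` of preprocessed (log, centered,
        scaled) concentrations.
    outcomes
        :class:`~bmfr.data.LongitudinalOutcomes` (mean-centered per outcome).
    covariates
        Optional :class:`~bmfr.data.CovariateTable` aligned with the outcome
        records.
    config
        :class:`~bmfr.config.ModelConfig`; ``seed`` must be set before `fit`.
    """

    def __init__(
        self,
        exposures: ExposurePanel,
        outcomes: LongitudinalOutcomes,
        covariates: CovariateTable | None = None,
        config: ModelConfig | None = None,
    ):
        self.exposures = exposures
        self.outcomes = outcomes
        self.covariates = covariates
        self.config = config if config is not None else ModelConfig()

    @classmethod
    def from_frames(
        cls,
        exposure_frame: pd.DataFrame,
        outcome_frame: pd.DataFrame,
        covariate_frame: pd.DataFrame | None = None,
        lod: dict | None = None,
        config: ModelConfig | None = None,
    ) -> "BayesianFactorRegression":
        exposures = ExposurePanel.from_frame(exposure_frame, lod=lod)
        outcomes = LongitudinalOutcomes.from_frame(
            outcome_frame, subject_order=exposures.subject_ids
        )
        covariates = (
            CovariateTable.from_frame(covariate_frame)
            if covariate_frame is not None
            else None
        )
        return cls(exposures, outcomes, covariates, config)

    @classmethod
    def from_csv(
        cls,
        exposure_path,
        outcome_path,
        covariate_path=None,
        lod_path=None,
        config: ModelConfig | None = None,
    ) -> "BayesianFactorRegression":
        lod = None
        if lod_path is not None:
            lod_frame = pd.read_csv(lod_path)
            lod = dict(zip(lod_frame["metabolite"], lod_frame["lod"]))
        cov = pd.read_csv(covariate_path) if covariate_path is not None else None
        return cls.from_frames(
            pd.read_csv(exposure_path), pd.read_csv(outcome_path), cov, lod, config
        )

    def fit(self, **config_overrides) -> "FactorRegressionResults":
        """Run the Gibbs sampler and wrap the stored draws."""
        config = (
            self.config.replace(**config_overrides)
            if config_overrides
            else self.config
        )
        draws = run_chain(self.exposures, self.outcomes, self.covariates, config)
        return FactorRegressionResults(self, draws, config)

    def select_dimensions(
        self, K_grid=(2, 3, 4), H_grid=(1, 2), folds: int = 6, **config_overrides
    ):
        """Grid search over (K, H) by subject-wise cross-validated MPSE."""
        config = (
            self.config.replace(**config_overrides)
            if config_overrides
            else self.config
        )
        return cv_grid_search(
            self.exposures, self.outcomes, self.covariates,
            K_grid, H_grid, folds, config,
        )


class FactorRegressionResults:
    """Posterior draws plus post-processing for a fitted factor regression."""

    def __init__(
        self,
        model: BayesianFactorRegression,
        draws: PosteriorDraws,
        config: ModelConfig,
    ):
        self.model = model
        self.draws = draws
        self.config = config
        self._aligned: PosteriorDraws | None = None

    # -- alignment and summaries -----------------------------------------

    def align(self) -> PosteriorDraws:
        """Aligned draws (label-switch/sign-resolved), computed once."""
        if self._aligned is None:
            self._aligned = match_align(self.draws)
        return self._aligned

    def effects(self, level: float = 0.95, aligned: bool = True) -> EffectSummary:
        draws = self.align() if aligned else self.draws
        return summarize_effects(
            draws,
            level=level,
            times=self.model.outcomes.grid,
            outcome_names=self.model.outcomes.outcome_names,
            metabolite_names=self.model.exposures.metabolite_names,
        )

    def induced_effects_mean(self, aligned: bool = True) -> np.ndarray:
        """Posterior-mean induced per-exposure effects, shape (q, p, T)."""
        return self.effects(aligned=aligned).exposure_mean

    def variable_importance(self, aligned: bool = True) -> pd.DataFrame:
        table = variable_importance(self.induced_effects_mean(aligned=aligned))
        table.index = self.model.exposures.metabolite_names
        return table

    # -- prediction -------------------------------------------------------

    def predict(
        self,
        X_new: np.ndarray,
        Z_new: np.ndarray | None = None,
        posterior_mean: bool = True,
    ) -> np.ndarray:
        """Mean outcome trajectories for new subjects, shape (m, T, q).

        Averages the per-draw plug-in prediction ``B(t) E[eta|x] + B_c z``
        over stored draws (random intercepts of unseen subjects are zero).
        When ``Z_new`` is omitted only the factor part is predicted.
        With ``posterior_mean=False`` returns the (S, m, T, q) per-draw
        array.
        """
        X_new = np.asarray(X_new, dtype=float)
        col_means = X_new.mean(axis=0)
        if np.any(np.abs(col_means) > 1.0) and X_new.shape[0] > 10:
            import logging

            logging.getLogger(__name__).warning(
                "X_new column means far from 0; did you preprocess new "
                "exposures like the training data?"
            )
        d = self.draws
        S = len(d)
        from .core import assemble_B

        preds = np.stack(
            [
                predict_outcomes(
                    X_new,
                    assemble_B(d.Lambda[s], d.U[s]),
                    d.Theta[s],
                    d.sigma_x2[s],
                    None if (d.get("Bc") is None or Z_new is None) else d.Bc[s],
                    Z_new,
                )
                for s in range(S)
            ]
        )
        return preds.mean(axis=0) if posterior_mean else preds

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        """Plain-text fit summary."""
        d = self.draws
        buf = io.StringIO()
        q, K = d.Theta.shape[2], self.config.K
        buf.write("Bayesian multivariate factor regression\n")
        buf.write("=" * 55 + "\n")
        buf.write(
            f"subjects: {self.model.exposures.n}   exposures: "
            f"{self.model.exposures.p}   outcomes: {self.model.outcomes.q}   "
            f"grid ages: {self.model.outcomes.T}\n"
        )
        buf.write(
            f"K={self.config.K} H={self.config.H}  draws stored: {len(d)}  "
            f"(iter={self.config.n_iter}, burn={self.config.n_burn}, "
            f"thin={self.config.thin}, seed={self.config.seed})\n"
        )
        if self.config.kappa_is_fixed:
            buf.write(f"kappa: fixed at {float(self.config.kappa):g}\n")
        else:
            buf.write(
                f"kappa: posterior mean {d.kappa.mean():.3g}  (acceptance "
                f"{d.meta.get('kappa_acceptance', 1.0):.2f})\n"
            )
        nu2 = d.nu2
        icc = nu2 / (nu2 + 1.0)
        buf.write(
            f"between-subject variance share nu2/(nu2+1): "
            f"median {np.median(icc):.3f}\n\n"
        )
        buf.write("posterior-mean aligned loadings (exposures x factors):\n")
        loadings = pd.DataFrame(
            self.align().mean("Theta"),
            index=self.model.exposures.metabolite_names,
            columns=[f"factor{k + 1}" for k in range(self.align().Theta.shape[2])],
        )
        buf.write(loadings.round(3).to_string() + "\n\n")
        buf.write("exposure importance (summed |induced effect|):\n")
        buf.write(
            self.variable_importance().sort_values("rank").round(3).to_string()
            + "\n"
        )
        return buf.getvalue()

    def save(self, directory) -> None:
        self.draws.save(directory)

    def plot_effects(self, path=None, level: float = 0.95):
        """Trajectory bands per (outcome, factor); see :mod:`bmfr.plots`."""
        from .plots import plot_effect_trajectories

        return plot_effect_trajectories(self.effects(level=level), path=path)

    def plot_loadings(self, path=None):
        from .plots import plot_loadings_heatmap

        return plot_loadings_heatmap(
            self.align().mean("Theta"),
            self.model.exposures.metabolite_names,
            path=path,
        )
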