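"""Posterior post-processing.

Factor models are identified only up to column permutation and sign, and
MCMC chains wander between these equivalent modes. `match_align` resolves
the ambiguity across stored draws; the summaries and importance ranks then
operate on aligned draws. `cv_grid_search` selects the factor and basis
dimensions by subject-partitioned cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import ModelConfig
from .core import assemble_B, induced_exposure_effects
from .data import CovariateTable, ExposurePanel, LongitudinalOutcomes
from .state import PosteriorDraws

logger = logging.getLogger(__name__)

__all__ = [
    "match_align",
    "EffectSummary",
    "summarize_effects",
    "variable_importance",
    "importance_scores",
    "cv_grid_search",
]


def _greedy_match(Theta: np.ndarray, pivot: np.ndarray):
    """Greedy column matching by maximal absolute inner product.

    Returns (perm, signs) such that ``Theta[:, perm] * signs`` aligns with
    the pivot. Each pivot column, in order, takes the unmatched draw column
    with the largest |inner product| (lowest index on ties), and the sign
    making the inner product nonnegative.
    """
    K = pivot.shape[1]
    inner = pivot.T @ Theta  # (K_pivot, K_draw)
    perm = np.empty(K, dtype=int)
    signs = np.empty(K)
    taken = np.zeros(K, dtype=bool)
    for k in range(K):
        scores = np.abs(inner[k]).copy()
        scores[taken] = -np.inf
        j = int(np.argmax(scores))  # argmax takes the lowest index on ties
        perm[k] = j
        signs[k] = 1.0 if inner[k, j] >= 0 else -1.0
        taken[j] = True
    return perm, signs


def match_align(draws: PosteriorDraws) -> PosteriorDraws:
    """Resolve label-switching and sign ambiguity across stored draws.

    The pivot is the draw whose loadings matrix is closest (in squared
    distance) to the elementwise median of all loadings draws. Each draw's
    columns are then greedily matched to the pivot's by absolute inner
    product without replacement, signs flipped to a nonnegative inner
    product, and the same permutation/signs applied to the factor scores and
    the factor axis of the basis functions (hence of ``B``). Fitted means
    are invariant.
    """
    if len(draws) < 2:
        raise ValueError("alignment needs at least 2 stored draws")
    Theta = draws.Theta  # (S, p, K)
    med = np.median(Theta, axis=0)
    dist = np.sum((Theta - med[None]) ** 2, axis=(1, 2))
    pivot = Theta[int(np.argmin(dist))]
    S, _, K = Theta.shape
    perms = np.empty((S, K), dtype=int)
    signs = np.empty((S, K))
    new = {k: v.copy() for k, v in draws.draws.items()}
    for s in range(S):
        perm, sign = _greedy_match(Theta[s], pivot)
        perms[s], signs[s] = perm, sign
        new["Theta"][s] = Theta[s][:, perm] * sign[None, :]
        if "eta" in new:
            new["eta"][s] = draws.eta[s][:, perm] * sign[None, :]
        if "U" in new:
            new["U"][s] = draws.U[s][:, perm, :] * sign[None, :, None]
    new["align_perm"] = perms
    new["align_sign"] = signs
    meta = dict(draws.meta, aligned=True)
    return PosteriorDraws(new, meta)


@dataclass
class EffectSummary:
    """Pointwise posterior summaries of time-varying effects.

    ``factor_*`` arrays have shape (q, K, T) — effect of one unit increase
    in each (aligned) latent factor on each outcome at each grid age;
    ``exposure_*`` arrays have shape (q, p, T) — induced effect of one unit
    increase in each preprocessed exposure.
    """

    times: np.ndarray
    factor_mean: np.ndarray
    factor_lo: np.ndarray
    factor_hi: np.ndarray
    exposure_mean: np.ndarray
    exposure_lo: np.ndarray
    exposure_hi: np.ndarray
    level: float
    outcome_names: list[str] | None = None
    metabolite_names: list[str] | None = None

    def __post_init__(self) -> None:
        for lo, mean, hi in (
            (self.factor_lo, self.factor_mean, self.factor_hi),
            (self.exposure_lo, self.exposure_mean, self.exposure_hi),
        ):
            if np.any(lo > mean + 1e-12) or np.any(mean > hi + 1e-12):
                raise ValueError("interval ordering violated (lo <= mean <= hi)")

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: (outcome, effect, age, mean, lo, hi)."""
        rows = []
        q, K, T = self.factor_mean.shape
        p = self.exposure_mean.shape[1]
        onames = self.outcome_names or [f"y{j}" for j in range(q)]
        mnames = self.metabolite_names or [f"x{j}" for j in range(p)]
        for j in range(q):
            for k in range(K):
                for t in range(T):
                    rows.append((onames[j], f"factor{k + 1}", self.times[t],
                                 self.factor_mean[j, k, t],
                                 self.factor_lo[j, k, t], self.factor_hi[j, k, t]))
            for m in range(p):
                for t in range(T):
                    rows.append((onames[j], mnames[m], self.times[t],
                                 self.exposure_mean[j, m, t],
                                 self.exposure_lo[j, m, t], self.exposure_hi[j, m, t]))
        return pd.DataFrame(rows, columns=["outcome", "effect", "age", "mean", "lo", "hi"])


def _draw_effect_arrays(draws: PosteriorDraws):
    """Per-draw factor-effect and induced-exposure-effect arrays."""
    S = len(draws)
    B = np.stack([assemble_B(draws.Lambda[s], draws.U[s]) for s in range(S)])
    induced = np.stack(
        [
            induced_exposure_effects(B[s], draws.Theta[s], draws.sigma_x2[s])
            for s in range(S)
        ]
    )
    return B, induced


def summarize_effects(
    draws: PosteriorDraws,
    level: float = 0.95,
    times: np.ndarray | None = None,
    outcome_names: list[str] | None = None,
    metabolite_names: list[str] | None = None,
) -> EffectSummary:
    """Posterior mean and equal-tailed interval for every effect cell.

    Quantiles use the default linear ("type 7") interpolation; with few
    draws the interval endpoints are interpolated order statistics and the
    interval lies within the sample range.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    B, induced = _draw_effect_arrays(draws)
    a = 0.5 * (1 - level)
    if times is None:
        times = np.arange(B.shape[-1], dtype=float)
    return EffectSummary(
        times=np.asarray(times, dtype=float),
        factor_mean=B.mean(axis=0),
        factor_lo=np.quantile(B, a, axis=0),
        factor_hi=np.quantile(B, 1 - a, axis=0),
        exposure_mean=induced.mean(axis=0),
        exposure_lo=np.quantile(induced, a, axis=0),
        exposure_hi=np.quantile(induced, 1 - a, axis=0),
        level=level,
        outcome_names=outcome_names,
        metabolite_names=metabolite_names,
    )


def importance_scores(effects: np.ndarray) -> np.ndarray:
    """Per-exposure importance: |effect| summed over outcomes and ages.

    ``effects`` is a (q, p, T) array of (posterior-mean) induced effects.
    """
    effects = np.asarray(effects)
    return np.abs(effects).sum(axis=(0, 2))


def variable_importance(effects: np.ndarray) -> pd.DataFrame:
    """Rank exposures by summed absolute effect (descending; ties share
    the mean rank)."""
    scores = importance_scores(effects)
    ranks = rankdata(-scores, method="average")
    return pd.DataFrame({"score": scores, "rank": ranks})


def cv_grid_search(
    exposures: ExposurePanel,
    outcomes: LongitudinalOutcomes,
    covariates: CovariateTable | None,
    K_grid,
    H_grid,
    folds: int,
    config: ModelConfig,
    *,
    standardize_within_folds: bool = True,
):
    """Choose (K, H) by subject-partitioned cross-validated MPSE.

    Subjects are shuffled with the config seed and split into ``folds``
    groups; candidate pairs respect H <= K. For each pair the model is fit
    on the training subjects and held-out subjects are predicted through the
    exposure-to-factor-score map; the score is the mean squared error over
    all held-out observed outcome entries. Folds are split by subject, never
    by visit, so random intercepts cannot leak.

    Returns ``(best_pair, table)`` where the table has one row per (K, H)
    with its MPSE.
    """
    from .model import BayesianFactorRegression  # local import, avoids cycle

    if folds < 2:
        raise ValueError("folds must be >= 2")
    pairs = [(K, H) for K in K_grid for H in H_grid if H <= K]
    if not pairs:
        raise ValueError("no admissible (K, H) pairs with H <= K")
    rng = np.random.default_rng(config.seed)
    n = exposures.n
    order = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    assignments[order] = np.arange(n) % folds
    results = []
    for K, H in pairs:
        sq_err_sum, n_cells = 0.0, 0
        for fold in range(folds):
            test_mask = assignments == fold
            err, m = _cv_fold_error(
                exposures, outcomes, covariates, test_mask,
                config.replace(K=K, H=H, seed=int(config.seed) + 1000 * fold),
                standardize_within_folds,
            )
            sq_err_sum += err
            n_cells += m
        results.append((K, H, sq_err_sum / max(n_cells, 1)))
        logger.info("cv pair K=%d H=%d mpse=%.4f", K, H, results[-1][2])
    table = pd.DataFrame(results, columns=["K", "H", "mpse"])
    best = table.loc[table["mpse"].idxmin()]
    return (int(best["K"]), int(best["H"])), table


def _cv_fold_error(exposures, outcomes, covariates, test_mask, config, standardize):
    from .model import BayesianFactorRegression

    train_mask = ~test_mask
    train_ids = np.nonzero(train_mask)[0]
    test_ids = np.nonzero(test_mask)[0]
    remap = -np.ones(exposures.n, dtype=int)
    remap[train_ids] = np.arange(len(train_ids))
    X = exposures.values
    if standardize:
        mu = X[train_ids].mean(axis=0)
        sd = X[train_ids].std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
        lod = None if exposures.lod is None else (exposures.lod - mu) / sd
    else:
        lod = exposures.lod
    exp_train = ExposurePanel(
        X[train_ids], lod, exposures.censored[train_ids],
        exposures.metabolite_names,
    )
    rec_train = train_mask[outcomes.subject_index]
    y = outcomes.y.copy()
    if standardize:
        y_mean = np.array([
            np.nanmean(np.where(outcomes.missing[rec_train][:, j], np.nan,
                                y[rec_train][:, j]))
            for j in range(outcomes.q)
        ])
        y = y - y_mean[None, :]
    out_train = LongitudinalOutcomes(
        y[rec_train], remap[outcomes.subject_index[rec_train]],
        outcomes.t_index[rec_train], outcomes.grid,
        outcomes.missing[rec_train], outcomes.ages[rec_train],
        outcomes.outcome_names,
    )
    cov_train = None
    if covariates is not None:
        cov_train = CovariateTable(
            covariates.z[rec_train], covariates.labels, covariates.is_dummy
        )
    model = BayesianFactorRegression(exp_train, out_train, cov_train, config)
    res = model.fit()
    rec_test = test_mask[outcomes.subject_index]
    test_subj_pos = {s: i for i, s in enumerate(test_ids)}
    Z_test = covariates.z[rec_test] if covariates is not None else None
    pred_grid = res.predict(X[test_ids])  # (m, T, q)
    rows = np.array([test_subj_pos[s] for s in outcomes.subject_index[rec_test]])
    pred = pred_grid[rows, outcomes.t_index[rec_test], :]
    if Z_test is not None:
        Bc_mean = res.draws.mean("Bc")
        pred = pred + Z_test @ Bc_mean.T
    obs = ~outcomes.missing[rec_test]
    truth = y[rec_test]
    err = float(np.sum((pred[obs] - truth[obs]) ** 2))
    return err, int(obs.sum())
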