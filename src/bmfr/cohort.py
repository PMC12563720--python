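"""Synthetic birth-cohort fixtures and preprocessing.

Generates data emulating a prenatal-exposure cohort: nine urinary phthalate
metabolites measured once per mother (log-normal, block-correlated into a
DEHP and a non-DEHP group, left-censored at metabolite-specific detection
limits), maternal covariates, up to three childhood follow-up visits at
ages 4-10 with dropout, and four positively correlated adiposity outcomes
(fat mass percentage, BMI z-score, waist-to-hip ratio, waist
circumference). An optional effect specification injects a time-varying
effect of the DEHP factor on all outcomes so the full pipeline can be
exercised end to end with a known truth.

Everything here is synthetic; no real cohort data are included or required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CovariateTable, ExposurePanel, LongitudinalOutcomes

__all__ = [
    "METABOLITES",
    "DEHP_GROUP",
    "OUTCOMES",
    "EffectSpec",
    "SyntheticCohort",
    "gen_cohort",
    "dilution_adjust",
    "preprocess",
]

DEHP_GROUP = ["MEHP", "MEHHP", "MEOHP", "MECPP"]
NON_DEHP_GROUP = ["MEP", "MnBP", "MiBP", "MCPP", "MBzP"]
METABOLITES = DEHP_GROUP + NON_DEHP_GROUP
OUTCOMES = ["FMP", "BMIz", "WHR", "WC"]

# log-scale geometric means (ng/mL-like), factor loadings and noise scales;
# within-group correlations ~0.7-0.8, echoing the strong block structure of
# urinary phthalate panels
_LOG_MEANS = {
    "MEHP": 1.6, "MEHHP": 3.0, "MEOHP": 2.7, "MECPP": 3.4,
    "MEP": 5.0, "MnBP": 3.4, "MiBP": 2.3, "MCPP": 1.0, "MBzP": 2.6,
}
_LOADING = 0.95
_NOISE_SD = 0.55
# z-scores of the detection limit below each metabolite's mean; MEHP is the
# least sensitive assay (harbors nearly all nondetects)
_LOD_Z = {
    "MEHP": -1.76, "MEHHP": -2.85, "MEOHP": -2.85, "MECPP": -2.85,
    "MEP": -2.85, "MnBP": -3.2, "MiBP": -2.35, "MCPP": -2.35, "MBzP": -2.85,
}
# analytical-standard correction factors applied at generation
_CORRECTION = {"MBzP": 0.72, "MEP": 0.66}


@dataclass
class EffectSpec:
    """Injected true effect of the DEHP factor on the outcomes.

    The trajectory is ``slope * (age - crossing_age)`` on the standardized
    outcome scale: negative before the crossing age, positive after, as a
    simple sign-changing time-varying effect.
    """

    slope: float = 0.25
    crossing_age: float = 7.0
    factor: str = "DEHP"  # "DEHP" or "nonDEHP"

    def trajectory(self, ages: np.ndarray) -> np.ndarray:
        return self.slope * (np.asarray(ages, dtype=float) - self.crossing_age)


@dataclass
class SyntheticCohort:
    """Raw synthetic cohort tables (natural scales, pre-preprocessing)."""

    exposures: pd.DataFrame  # mother_id + 9 natural-scale concentrations
    lods: pd.Series  # per-metabolite natural-scale LOD
    censored: pd.DataFrame  # mother_id + boolean nondetect flags
    creatinine: pd.Series  # observed creatinine per mother
    covariates: pd.DataFrame  # one row per mother
    visits: pd.DataFrame  # mother_id, age_months, FMP, BMIz, WHR, WC
    meta: dict = field(default_factory=dict)
    eta_true: np.ndarray | None = None  # (n, 2) latent factors (DEHP, nonDEHP)

    @property
    def n(self) -> int:
        return len(self.exposures)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.exposures.to_csv(directory / "exposures.csv", index=False)
        pd.DataFrame(
            {"metabolite": self.lods.index, "lod": self.lods.values}
        ).to_csv(directory / "lod.csv", index=False)
        self.censored.to_csv(directory / "censored.csv", index=False)
        self.covariates.assign(creatinine=self.creatinine.values).to_csv(
            directory / "covariates.csv", index=False
        )
        self.visits.to_csv(directory / "outcomes.csv", index=False)
        import json

        (directory / "manifest.json").write_text(json.dumps(self.meta, indent=2))


def gen_cohort(
    n_mothers: int = 382,
    retention: float = 0.47,
    seed: int = 0,
    effect_spec: EffectSpec | None = None,
) -> SyntheticCohort:
    """Generate a synthetic cohort.

    Parameters
    ----------
    n_mothers
        Number of mothers with measured metabolites (>= 20).
    retention
        Fraction of children with at least one follow-up visit, in (0, 1].
        At ``retention=1`` every child attends all three waves.
    seed
        RNG seed; all cohort randomness derives from it.
    effect_spec
        Optional injected DEHP-factor effect; ``None`` makes outcomes
        independent of the exposures.
    """
    if n_mothers < 20:
        raise ValueError("need n_mothers >= 20")
    if not (0 < retention <= 1):
        raise ValueError("retention must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = n_mothers
    p = len(METABOLITES)

    # --- exposures: 2-factor log-normal with block structure
    eta = rng.standard_normal((n, 2))  # (DEHP factor, non-DEHP factor)
    logc = np.empty((n, p))
    lod_nat = np.empty(p)
    for j, name in enumerate(METABOLITES):
        fac = eta[:, 0] if name in DEHP_GROUP else eta[:, 1]
        load = _LOADING * (1.0 + 0.1 * rng.standard_normal())
        logc[:, j] = (
            _LOG_MEANS[name] + load * fac + _NOISE_SD * rng.standard_normal(n)
        )
        total_sd = np.hypot(load, _NOISE_SD)
        lod_nat[j] = np.exp(_LOG_MEANS[name] + _LOD_Z[name] * total_sd)
    conc = np.exp(logc)
    for name, corr in _CORRECTION.items():
        j = METABOLITES.index(name)
        conc[:, j] *= corr
        lod_nat[j] *= corr
    censored = conc < lod_nat[None, :]
    conc_export = np.where(censored, lod_nat[None, :], conc)

    # --- maternal covariates (marginals echo the study population)
    age = rng.normal(24.4, 6.4, n).clip(15, 45)
    bmi = rng.normal(23.9, 4.7, n).clip(15, 45)
    gwg = rng.choice(["inadequate", "adequate", "excessive"], n, p=[0.25, 0.35, 0.4])
    smoking = rng.random(n) < 0.17
    education = rng.random(n) < 0.22
    race = rng.choice(["white", "black", "hispanic_other"], n, p=[0.18, 0.28, 0.54])
    breastfed = rng.random(n) < 0.63
    sex = rng.random(n) < 0.51  # True = male
    birthweight = rng.normal(3296, 458, n).clip(1500, 5000)
    covariates = pd.DataFrame(
        {
            "mother_id": np.arange(n),
            "maternal_age": age,
            "maternal_bmi": bmi,
            "gwg_category": gwg,
            "smoking": smoking.astype(int),
            "college_education": education.astype(int),
            "race": race,
            "breastfed": breastfed.astype(int),
            "child_male": sex.astype(int),
            "birthweight": birthweight,
        }
    )

    # --- creatinine depends linearly on maternal covariates (log scale)
    log_creat = (
        4.6
        + 0.01 * (age - 24.4)
        + 0.02 * (bmi - 23.9)
        - 0.1 * smoking
        + 0.05 * education
        + 0.3 * rng.standard_normal(n)
    )
    creatinine = np.exp(log_creat)

    # --- visits: three waves, dropout
    wave_windows = [(48, 66), (68, 84), (84, 122)]  # months
    returner = rng.random(n) < retention if retention < 1 else np.ones(n, bool)
    rows = []
    for i in range(n):
        if not returner[i]:
            continue
        if retention >= 1:
            attended = [True, True, True]
        else:
            attended = list(rng.random(3) < 0.62)
            if not any(attended):
                attended[rng.integers(3)] = True
        for w, (lo, hi) in enumerate(wave_windows):
            if attended[w]:
                rows.append((i, float(rng.uniform(lo, hi))))
    visit_frame = pd.DataFrame(rows, columns=["mother_id", "age_months"])

    # --- outcomes: shared child-adiposity factor drives positive
    # correlations, WHR loading smallest; optional injected DEHP effect
    out_mean = {"FMP": 25.0, "BMIz": 0.3, "WHR": 0.90, "WC": 56.0}
    out_sd = {"FMP": 6.0, "BMIz": 1.0, "WHR": 0.05, "WC": 7.0}
    share = {"FMP": 0.85, "BMIz": 0.85, "WHR": 0.45, "WC": 0.85}
    child_factor = rng.standard_normal(n)
    m = len(visit_frame)
    ages_y = visit_frame["age_months"].to_numpy() / 12.0
    idx = visit_frame["mother_id"].to_numpy(dtype=int)
    effect = np.zeros(m)
    if effect_spec is not None:
        fac = eta[:, 0] if effect_spec.factor == "DEHP" else eta[:, 1]
        effect = effect_spec.trajectory(ages_y) * fac[idx]
    age_trend = 0.08 * (ages_y - 7.0)  # mild common growth trend (sd units)
    for name in OUTCOMES:
        c = share[name]
        z = (
            c * child_factor[idx]
            + age_trend
            + effect
            + np.sqrt(max(1 - c**2, 0.05)) * rng.standard_normal(m)
        )
        raw = out_mean[name] + out_sd[name] * z
        if name == "WC":
            raw = np.maximum(raw, 30.0)  # keep log-transformable
        if name == "WHR":
            raw = np.maximum(raw, 0.6)
        visit_frame[name] = raw
    # a sprinkle of missing outcome cells, as seen at real visits
    for name in ("FMP", "BMIz"):
        k = rng.binomial(m, 0.006)
        if k:
            visit_frame.loc[rng.choice(m, k, replace=False), name] = np.nan

    exposures = pd.DataFrame(conc_export, columns=METABOLITES)
    exposures.insert(0, "mother_id", np.arange(n))
    cens_frame = pd.DataFrame(censored, columns=METABOLITES)
    cens_frame.insert(0, "mother_id", np.arange(n))
    meta = {
        "n_mothers": n_mothers,
        "retention": retention,
        "seed": seed,
        "effect_spec": None
        if effect_spec is None
        else {"slope": effect_spec.slope, "crossing_age": effect_spec.crossing_age,
              "factor": effect_spec.factor},
        "n_children_followed": int(returner.sum()),
        "n_visits": int(m),
    }
    return SyntheticCohort(
        exposures, pd.Series(lod_nat, index=METABOLITES), cens_frame,
        pd.Series(creatinine, name="creatinine"), covariates, visit_frame,
        meta, eta,
    )


def dilution_adjust(
    concentrations: pd.DataFrame,
    creatinine: np.ndarray,
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Standardize concentrations for urine dilution by the Cratio.

    Fits an internal linear regression of log creatinine on the maternal
    covariates, forms Cratio_i = predicted_i / observed_i and multiplies
    each mother's natural-scale concentrations by her Cratio. Returns the
    adjusted table and the fitted coefficients.
    """
    creatinine = np.asarray(creatinine, dtype=float)
    if np.any(creatinine <= 0):
        raise ValueError("creatinine must be positive")
    design, names = _creatinine_design(covariates)
    coefs, *_ = np.linalg.lstsq(design, np.log(creatinine), rcond=None)
    predicted = np.exp(design @ coefs)
    cratio = predicted / creatinine
    value_cols = [c for c in concentrations.columns if c != "mother_id"]
    adjusted = concentrations.copy()
    adjusted[value_cols] = adjusted[value_cols].to_numpy() * cratio[:, None]
    return adjusted, {"coef": dict(zip(names, coefs)), "cratio": cratio}


def _creatinine_design(covariates: pd.DataFrame):
    cols = ["maternal_age", "maternal_bmi", "smoking", "college_education"]
    parts = [np.ones(len(covariates))]
    names = ["intercept"]
    for c in cols:
        v = covariates[c].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            import warnings

            warnings.warn(f"dropping constant covariate {c} from creatinine model")
            continue
        parts.append(v)
        names.append(c)
    for cat_col in ("gwg_category", "race"):
        if cat_col in covariates:
            dummies = pd.get_dummies(covariates[cat_col], prefix=cat_col, drop_first=True)
            for c in dummies.columns:
                parts.append(dummies[c].to_numpy(dtype=float))
                names.append(c)
    return np.column_stack(parts), names


def preprocess(cohort: SyntheticCohort):
    """Build model-ready inputs from a raw cohort.

    Exposures are dilution-adjusted, log-transformed and standardized; WC is
    log-transformed; every outcome is mean-centered; continuous covariates
    are standardized and categorical ones dummy-coded; visit ages are
    rounded to integer years, which defines the discrete time grid. The
    censoring mask is carried through, with each metabolite's effective
    log-scale bound taken as the largest transformed bound among its
    censored cells (the bound is mother-specific after the Cratio
    adjustment; the per-metabolite envelope is a documented approximation).

    Returns ``(ExposurePanel, LongitudinalOutcomes, CovariateTable)``.
    """
    adjusted, creat_info = dilution_adjust(
        cohort.exposures, cohort.creatinine.to_numpy(), cohort.covariates
    )
    value_cols = METABOLITES
    conc = adjusted[value_cols].to_numpy(dtype=float)
    if np.any(conc <= 0):
        raise ValueError("nonpositive concentration after adjustment")
    cens = cohort.censored[value_cols].to_numpy(dtype=bool)
    cratio = creat_info["cratio"]
    logx = np.log(conc)
    mu, sd = logx.mean(axis=0), logx.std(axis=0)
    sd[sd == 0] = 1.0
    z = (logx - mu) / sd
    # per-cell transformed censoring bound -> per-metabolite envelope
    lod_nat = cohort.lods.reindex(value_cols).to_numpy()
    cell_bound = (np.log(lod_nat[None, :] * cratio[:, None]) - mu) / sd
    lod_final = np.where(
        cens.any(axis=0),
        np.max(np.where(cens, cell_bound, -np.inf), axis=0),
        cell_bound.mean(axis=0),
    )
    z = np.where(cens, np.minimum(z, lod_final[None, :]), z)
    panel = ExposurePanel(
        z, lod_final, cens, list(value_cols),
        cohort.exposures["mother_id"].to_numpy(),
    )

    visits = cohort.visits.copy()
    visits["age"] = visits["age_months"] / 12.0
    y = visits[OUTCOMES].to_numpy(dtype=float)
    y = y.copy()
    wc = y[:, OUTCOMES.index("WC")]
    y[:, OUTCOMES.index("WC")] = np.log(wc)
    col_means = np.nanmean(y, axis=0)
    y = y - col_means[None, :]
    out_frame = pd.DataFrame(y, columns=OUTCOMES)
    out_frame.insert(0, "age", visits["age"].to_numpy())
    out_frame.insert(0, "subject_id", visits["mother_id"].to_numpy())
    outcomes = LongitudinalOutcomes.from_frame(
        out_frame, subject_order=cohort.exposures["mother_id"].to_numpy()
    )

    cov = cohort.covariates
    rec = visits["mother_id"].to_numpy(dtype=int)
    cont = ["maternal_age", "maternal_bmi", "birthweight"]
    parts, labels = [], []
    for c in cont:
        v = cov[c].to_numpy(dtype=float)
        parts.append((v - v.mean()) / v.std())
        labels.append(c)
    creat = np.log(cohort.creatinine.to_numpy())
    parts.append((creat - creat.mean()) / creat.std())
    labels.append("log_creatinine")
    for c in ("smoking", "college_education", "breastfed", "child_male"):
        parts.append(cov[c].to_numpy(dtype=float))
        labels.append(c)
    for cat_col in ("gwg_category", "race"):
        dummies = pd.get_dummies(cov[cat_col], prefix=cat_col, drop_first=True)
        for c in dummies.columns:
            parts.append(dummies[c].to_numpy(dtype=float))
            labels.append(c)
    z_subj = np.column_stack(parts)  # per mother
    covariate_table = CovariateTable(z_subj[rec][outcomes_record_mask(visits, y)], labels)
    return panel, outcomes, covariate_table


def outcomes_record_mask(visits: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    """Records kept by the outcome loader (drops all-missing rows)."""
    return ~np.all(~np.isfinite(y), axis=1)


def dehp_factor_trajectory(results) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-mean trajectory of the DEHP factor's effect over age.

    Identifies the aligned factor with the largest summed |loading| on the
    DEHP-group metabolites, orients it so the DEHP loadings sum positive
    (one latent unit = higher DEHP exposure), and returns
    ``(grid ages, trajectory)`` where the trajectory averages the factor's
    effect across outcomes at each grid age.
    """
    aligned = results.align()
    Theta_mean = aligned.mean("Theta")  # (p, K)
    names = results.model.exposures.metabolite_names
    dehp_rows = [i for i, m in enumerate(names) if m in DEHP_GROUP]
    scores = np.abs(Theta_mean[dehp_rows]).sum(axis=0)
    k = int(np.argmax(scores))
    sign = 1.0 if Theta_mean[dehp_rows, k].sum() >= 0 else -1.0
    eff = results.effects(aligned=True)
    traj = sign * eff.factor_mean[:, k, :].mean(axis=0)  # (T,)
    return results.model.outcomes.grid, traj
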