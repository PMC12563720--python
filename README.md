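# bmfr — Bayesian multivariate factor regression for exposure mixtures

`bmfr` estimates the time-varying health effects of a correlated chemical
exposure mixture on multiple correlated longitudinal outcomes. It was
built for prenatal-exposure epidemiology: urinary phthalate metabolite
concentrations measured once in pregnancy (nine metabolites that cluster
into a DEHP and a non-DEHP group), and childhood adiposity outcomes — fat
mass percentage, BMI z-score, waist-to-hip ratio, waist circumference —
measured at irregular follow-up ages. The same machinery applies to any
mixture-plus-longitudinal-outcomes design.

## The model

Exposures are summarized by latent factors,

    x_i  ~ N_p(Θ η_i, Σ_X),      η_i ~ N_K(0, I),   Σ_X diagonal,

with a multiplicative gamma process (MGP) prior on the loadings Θ that
shrinks unneeded factor columns. Outcomes follow

    y_it ~ N_q(B(t) η_i + B_c z_it + ξ_i, Σ_Y),     ξ_i ~ N_q(0, ν² Σ_Y),

where the q×K coefficient matrix B(t) varies smoothly over a discrete age
grid through a low-rank Gaussian-process expansion B(t) = Λ U(t): each row
u_hk of U has a GP prior with squared-exponential kernel
exp(−½((t−t′)/κ)²) (unit amplitude; shared length scale κ, fixed or given
a uniform prior on a grid), and Λ carries its own MGP prior so effects are
correlated across outcomes. Covariate coefficients B_c get a horseshoe-type
global–local shrinkage prior; ν has a half-Cauchy prior; Σ_Y an
inverse-Wishart. Estimation is by a Gibbs sampler with fully conjugate
blocks; below-detection-limit exposures and missing outcomes are imputed
inside the sampler (truncated-normal and conditional-Gaussian draws), so
their uncertainty propagates into the credible bands.

Effects are reported per latent factor and, via the conditional-expectation
map E[η|x] = (Θ'Σ_X⁻¹Θ + I)⁻¹Θ'Σ_X⁻¹ x, as induced effects of each
individual exposure. Exposures are ranked by the absolute induced effect
summed over ages and outcomes.

## Worked example

No real cohort data ship with the package; `bmfr.cohort` generates a
synthetic cohort with the same structure (block-correlated log-normal
metabolites with detection limits, up to three follow-up visits at ages
4–10 with dropout, four positively correlated adiposity outcomes) and can
inject a known sign-changing effect of the DEHP factor:

```python
from bmfr import BayesianFactorRegression, ModelConfig
from bmfr.cohort import EffectSpec, dehp_factor_trajectory, gen_cohort, preprocess

cohort = gen_cohort(n_mothers=382, retention=0.47, seed=7,
                    effect_spec=EffectSpec(slope=0.25))
panel, outcomes, covariates = preprocess(cohort)
config = ModelConfig(K=3, H=2, kappa=6.0, n_iter=2000, n_burn=1000,
                     thin=5, seed=11)
res = BayesianFactorRegression(panel, outcomes, covariates, config).fit()
print(res.summary())
```

prints (abridged):

```
subjects: 382   exposures: 9   outcomes: 4   grid ages: 7
K=3 H=2  draws stored: 200  (iter=2000, burn=1000, thin=5, seed=11)
kappa: fixed at 6
between-subject variance share nu2/(nu2+1): median 0.035

posterior-mean aligned loadings (exposures x factors):
       factor1  factor2  factor3
MEHP    -0.099   -0.852   -0.094
MEHHP   -0.074   -0.830   -0.019
MEOHP   -0.072   -0.824   -0.033
MECPP   -0.044   -0.856   -0.019
MEP     -0.848   -0.075   -0.014
MnBP    -0.840   -0.018   -0.028
MiBP    -0.868   -0.057    0.001
MCPP    -0.886   -0.031    0.007
MBzP    -0.868   -0.031    0.013
```

The sampler recovers the two metabolite groups as factors (columns 1 and 2;
signs are arbitrary up to the alignment convention). The injected DEHP
effect — negative before age 7, positive after — is recovered by

```python
ages, traj = dehp_factor_trajectory(res)
```

```
age 4: -1.311   age 5: -0.986   age 6: -0.627   age 7: -0.263
age 8: +0.080   age 9: +0.378   age 10: +0.615
```

`res.effects()` returns posterior means with 95% equal-tailed bands for
every (outcome, factor, age) and (outcome, metabolite, age) cell;
`res.plot_effects(...)` and `res.plot_loadings(...)` write the
corresponding figures, and `res.variable_importance()` the per-metabolite
ranking.

A command-line interface wraps the same pipeline:

```bash
bmfr simulate-cohort --n-mothers 382 --retention 0.47 --seed 5 --out cohort/
bmfr fit --exposures X.csv --outcomes Y.csv --covariates Z.csv \
         --lod lod.csv --seed 3 --sex-stratify --out fit/
bmfr benchmark --scenario 2 --reps 20 --seed 1 --methods oracle,mean,pca_lmm --out bench/
```

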