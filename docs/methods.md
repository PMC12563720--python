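# Methods

## Model

Let `x_i` (length p) be a subject's preprocessed exposure vector (log
concentration, dilution-adjusted, centered and scaled) and `y_it` (length
q) their outcome vector at visit t on a discrete age grid `t = 1..T`
formed by rounding visit ages to whole years.

Exposure factor model

    x_i ~ N_p(Θ η_i, Σ_X),  η_i ~ N_K(0, I_K),  Σ_X = diag(σ²_1..σ²_p)

* `θ_jk ~ N(0, φ_jk⁻¹ τ_k⁻¹)`, `φ_jk ~ Ga(v/2, v/2)` with `v = 3`,
  `τ_k = Π_{l≤k} δ_l`, `δ_1 ~ Ga(a₁, 1)`, `δ_{l≥2} ~ Ga(a₂, 1)` with
  `a₁ = 2.1, a₂ = 3.1` — the multiplicative gamma process (MGP), which
  shrinks later columns progressively so K only needs to be large enough.
* `σ²_j ~ InvGamma(2, b)` with the rate `b ≈ 0.1486` solved numerically so
  that P(σ²_j < 1) = 0.99: exposures have unit variance, so idiosyncratic
  noise should not exceed the total.

Outcome model

    y_it ~ N_q(B(t) η_i + B_c z_it + ξ_i, Σ_Y),  ξ_i ~ N_q(0, ν² Σ_Y)

* `B(t) = Λ U(t)` with `Λ` (q×H, H ≤ K) carrying a second MGP prior and
  each basis row `u_hk` a zero-mean Gaussian process over the grid with
  kernel `c_κ(t,t') = exp(−½((t−t')/κ)²)`; the amplitude is fixed at 1
  (all magnitude lives in Λ) and κ is shared across rows. κ is either
  fixed (default 6 years — effects that drift over the span of childhood
  rather than oscillate) or given a uniform prior on a user grid and
  updated by exact discrete Gibbs. κ is a length-scale *divisor*; a
  multiplier convention (`exp(−½((t−t')κ)²)`) is selectable via
  `kappa_convention` for users who parameterize wiggliness inversely.
* `B_c ~ MN_{q×L}(0, Σ_Y, Ψ)`, `Ψ = diag(ψ_l)`, `ψ_l ~ Ga(u, ζ_l)`,
  `ζ_l ~ Ga(v, r)` with `u = v = 1/2` (horseshoe-type column selection)
  and global rate `r = 1/(K n ln n)` by default.
* `Σ_Y ~ InvWishart(s₀, S₀)`; by default `S₀` is the sample covariance of
  the outcomes and `s₀ = 6`, centering the prior loosely on the data scale.
* `ν` has a half-Cauchy prior (default scale 25), implemented by the
  inverse-gamma parameter expansion `ν²|a ~ IG(½, 1/a)`,
  `a ~ IG(½, 1/A²)`. `ν²/(ν²+1)` is the share of residual variation
  attributable to stable between-subject differences.
* ξ_i is q-dimensional (it is added to the q-vector mean and scaled by the
  q×q Σ_Y).

## Gibbs sampler

All full conditionals are conjugate; each sweep runs, in order:
truncated-normal re-imputation of below-LOD exposures, conditional-Gaussian
re-imputation of missing outcome coordinates (using the full model mean —
factor, covariate and intercept parts — in both the missing-coordinate
mean and the observed-residual term), then η, the Θ/σ²/MGP block, the
U/Λ/MGP block, the B_c/ψ/ζ block, the ξ/ν²/Σ_Y block, and κ. Imputations
run first so every block conditions on complete data; the update order is
otherwise immaterial at stationarity.

Noteworthy conditionals:

* η_i: precision `I + Θ'Σ_X⁻¹Θ + Σ_t B(t)'Σ_Y⁻¹B(t)` over the subject's
  visits; batched across subjects with a vectorized Cholesky.
* u_hk: because each outcome record touches exactly one grid time, the
  likelihood precision is diagonal over the grid, and the conditional is a
  T-dimensional Gaussian with prior precision C⁻¹.
* vec(Λ): drawn jointly (dimension qH) since a non-diagonal Σ_Y couples
  the rows.
* ψ_l: generalized-inverse-Gaussian `GIG(u − q/2, b_l'Σ_Y⁻¹b_l, 2ζ_l)`,
  sampled through scipy's exact `geninvgauss` with the standard rescaling.
* Σ_Y: inverse-Wishart aggregating the outcome residuals, the scaled
  intercepts, and the B_c columns (whose prior row covariance is Σ_Y), with
  degrees of freedom `s₀ + N + n + L`.
* κ (grid mode): exact categorical draw ∝ the GP prior density of all HK
  basis rows under each candidate kernel. When a continuous interval is
  configured instead, a log-scale random-walk Metropolis step with
  Robbins–Monro adaptation targeting 0.44 acceptance is used, adaptation
  frozen after burn-in.

Numerical policies: Cholesky factorizations retry with escalating diagonal
jitter from 1e−10·mean(diag) up to 8 decades before raising; truncated
normals use scipy's inverse-CDF sampler (no rejection loops, stable in deep
tails); GIG arguments are floored at 1e−12 to avoid underflow in the
horseshoe spike (prior mass below the floor is ~1e−6); all stored draws
pass a finite-value guard. Chains are deterministic given `seed`:
identical seed, config and data reproduce draws bitwise.

Correctness is established by (a) per-block conjugacy oracles — frozen-
block draws versus closed-form or dense-grid conditional moments at 1%
tolerance — and (b) a joint-distribution (Geweke-style) test on a tiny
configuration (n=5, p=2, q=2, K=H=1, T=3, L=1): forward prior/likelihood
simulation versus successive-conditional Gibbs simulation, compared on
eleven marginal statistics by z-score with batch-means standard errors
(threshold |z| < 4 at 1e5 sweeps). The test configuration uses a
half-Cauchy scale of 1 for ν: the check's validity is config-independent,
and a tight scale keeps the ν² excursions short enough for honest
Monte-Carlo error; statistics with heavy-tailed marginals (ν², B_c) enter
through log or tanh transforms so their moments exist.

## Post-processing

Factor models are identified only up to column permutation and sign.
`match_align` picks as pivot the stored draw closest in squared distance to
the elementwise-median loadings, then greedily matches each draw's columns
to the pivot's by largest absolute inner product without replacement
(lowest index wins ties) and flips signs to nonnegative inner product; the
identical permutation and signs are applied to the factor scores and to
the factor axis of U, so fitted means are invariant to machine precision.
Credible intervals are equal-tailed sample quantiles with linear ("type
7") interpolation. Exposure importance is the absolute posterior-mean
induced effect summed over grid ages and outcomes, ranked descending with
mean-rank ties.

K and H are chosen by subject-partitioned cross-validation (never split by
visit, so random intercepts cannot leak): subjects are shuffled with the
config seed into folds, candidate pairs respect H ≤ K, held-out subjects
are predicted through the E[η|x] map, and the pair with the smallest MPSE
over held-out observed cells wins. Exposure standardization and outcome
centering are refit inside each training fold by default. Grid ages absent
from a training fold are handled implicitly by the GP prior, which is
defined over the full grid.

## Synthetic cohort generator

`bmfr.cohort.gen_cohort` emulates the structure of a prenatal phthalate
cohort: nine log-normal metabolites driven by a DEHP factor (MEHP, MEHHP,
MEOHP, MECPP) and a non-DEHP factor (MEP, MnBP, MiBP, MCPP, MBzP) with
within-group correlations ≈ 0.75; per-metabolite detection limits placed
so nondetects concentrate in MEHP (≈ 4% of samples) with scattered
nondetects elsewhere; analytical-standard correction factors (0.72 for
MBzP, 0.66 for MEP) applied at generation so the preprocessing stays
cohort-agnostic; maternal covariates with realistic marginals; creatinine
generated from a linear model on maternal covariates; up to three
follow-up waves at 48–122 months with dropout (a `retention` fraction of
children return at least once); and four adiposity outcomes driven by a
shared child-level factor with the waist-to-hip ratio loading weakest, so
all outcome correlations are positive and WHR's are smallest. An optional
`EffectSpec` injects a DEHP-factor effect `slope·(age − crossing_age)` on
the standardized outcome scale — negative before the crossing age,
positive after.

What the generator does *not* emulate: genuinely nonlinear dose-response,
informative (outcome-dependent) dropout, covariate missingness, assay
batch effects, or seasonal exposure variation. Passing end-to-end tests
therefore demonstrates correct inference under the model's assumptions,
not robustness to their violation.

Preprocessing mirrors standard practice: concentrations are standardized
for urine dilution by the creatinine ratio (predicted/observed from an
internal linear regression of log creatinine on maternal covariates),
log-transformed and standardized; waist circumference is log-transformed;
all outcomes are mean-centered; continuous covariates standardized and
categorical ones dummy-coded; visit ages rounded to integer years to form
the grid. Because the dilution adjustment is mother-specific, the
censoring bound after preprocessing differs by cell; the sampler's
per-metabolite bound is taken as the largest transformed bound among that
metabolite's censored cells — a slightly loose envelope, documented here
as an approximation.

## Simulation benchmark

Three scenarios, each with p=10 exposures from a sparse two-factor model
(disjoint blocks of five metabolites, nonzero loadings N(0,1), unit
idiosyncratic noise), q=5 outcomes at ten equally spaced times t=0..9 for
n=200 training and 200 test subjects:

1. linear factor effects with a linear time interaction
   (`g = b₁'η + (b₂'η)t`, b₁ ~ U(−3,3), b₂ ~ U(−0.5,0.5)), independent
   residuals C_ξ = I, C_ε = 0.5 I;
2. nonlinear smooth time-varying effects through a logistic and a
   Gaussian-bump basis (`g = β u(t)'η`, β ~ N(0,1),
   u₁ = 3.5/(1+e^{−3t+25}), u₂ = 9φ((t−5.5)/1.5)), compound-symmetric
   residuals with correlation 0.7 and per-coordinate variances 1 (ξ) and
   0.5 (ε) — the model's own regime;
3. a quadratic/interaction surface in the exposures themselves with
   two-sided-uniform coefficients and independent residuals. The surface
   acts on variance-standardized exposures: raw-scale quadratics would put
   fourth moments of the random loadings into the outcome variance and
   make replicate-to-replicate variability explode, which no stable
   benchmark table could exhibit.

Methods: the *oracle* predicts with the true surface g; the *mean model*
predicts each outcome's pooled training mean; *PCA-LMM* takes the first
4 = K*+2 principal components of the standardized training exposures and
fits one random-intercept linear mixed model per outcome with PC and time
fixed effects (maximum likelihood; statsmodels' default optimizer; OLS
fallback on numerical failure), predicting test subjects from fixed
effects only and mapping PC coefficients back to exposures as V·β̂ (its
printed two-stage form); the *factor regression* uses K=4, H=2, a κ grid
{1,2,4,6}, 3,000-iteration chains with 1,500 burn-in and thinning 5, with
exposures standardized and outcomes centered by training statistics.

Scored quantities: MPSE over all test (subject, time, outcome) cells, and
the Spearman correlation between the true and inferred per-exposure
importance ranks. True importance in scenarios 1–2 is the absolute induced
effect of the generating coefficients summed over times and outcomes
(through the population E[η|x] map); in scenario 3 it is the Monte-Carlo
mean absolute partial derivative of g. Estimated importance is computed on
each method's native effect scale — the standardized-exposure scale both
methods model — not rescaled to raw units: the per-metabolite sd factor
`sqrt(1+θ_j²)` is non-monotone in the loading and rescaling by it
scrambles ranks without changing what either method actually estimates.

Replicate seeds spawn deterministically from one master seed, so the whole
table reproduces bitwise. Problem sizes in the shipped checks — 20
replicates for the closed-form comparators, 6–10 replicates of
3,000-iteration chains for the sampler-based rows, 10 end-to-end cohort
runs at n=400 with 800-iteration chains — were chosen to keep Monte-Carlo
error a fraction of each quantity's replicate spread while a full run
stays in the minutes range on one CPU.

One benchmark note: our PCA-LMM implementation predicts scenario 1
noticeably *better* (MPSE ≈ 5.4) than the level some published two-stage
comparisons report for this design; none of the defensible protocol
variants we tried (with/without PC×time interactions, PC count,
covariance- vs correlation-scale PCA) degrades it to that level while
staying consistent with its behavior in the other scenarios. The
comparator here is simply a competently fitted two-stage baseline.

## Limitations

* Linear in the factors: no nonlinear dose-response surface in the
  exposures; interactions would need explicit basis terms in z.
* K and H are fixed within a fit (the MGP shrinks surplus columns but does
  not truncate); selection is by cross-validation.
* One chain per fit; no convergence diagnostics beyond draw export
  (the saved draw directories are consumable by external diagnostic
  tooling), no marginal likelihood, no parallel tempering.
* The per-metabolite censoring bound after subject-specific dilution
  adjustment is an envelope (see above).
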