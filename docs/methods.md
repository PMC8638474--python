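# Methods

`qintreg` estimates how household and child covariates, child age, preceding
birth interval (PBI), region and survey year shape the *upper tail* of the
BMI-for-age z-score (BMIAZ) distribution in young children — the tail where
overweight (2 ≤ BMIAZ ≤ 3) and obesity (BMIAZ > 3) live.  Rather than a
single quantile level, it reports **quantile-interval weighted estimates**:
fits at a grid of levels τ₀ < … < τₙ inside [τ\*−Δτ\*, τ\*+Δτ\*] are combined
with normalised weights ωⱼ,

    β̂ᵢ(τ*±Δτ*) = Σⱼ ωⱼ β̂ᵢⱼ(τⱼ),        ĝᵢ(τ*±Δτ*) = Σⱼ ωⱼ ĝᵢⱼ(τⱼ),

for fixed effects and smooth/spatio-temporal functions respectively.  The
upper-tail convention for overweight is τ\* = 0.92, Δτ\* = 0.07, i.e. the
interval [0.85, 0.99]; with the default grid step 0.01 that is 15 levels.
Setting Δτ\* = 0 recovers an ordinary single-quantile analysis exactly.

## The single-τ model

Each level τ is fitted as a three-level latent Gaussian model with a working
asymmetric-Laplace (AL) likelihood,

    y_i ~ AL(η_i, σ, τ),
    η_i = x_i'β + g_age(a_i) + g_pbi(p_i) + u_{r(i)} + v_{t(i)},

whose maximum-likelihood location is the conditional τ-quantile.  Latent
priors:

| term            | prior                       | constraint   |
|-----------------|-----------------------------|--------------|
| fixed effects β | N(0, 1/0.001) each          | —            |
| g_age (0–59 mo) | RW1 or RW2, knot per month  | sum-to-zero  |
| g_pbi           | RW1 or RW2 on observed months | sum-to-zero |
| spatial u       | ICAR, PCAR (D − ρA) or IID  | sum-to-zero (ICAR) |
| temporal v      | RW1/RW2 over survey years   | sum-to-zero  |

Precision hyperparameters carry Gamma(1, 5·10⁻⁵) priors (a log-gamma prior on
the log precision); the PCAR autocorrelation ρ gets a Beta prior on (0, 1)
(logit-beta on the logit scale); the AL scale σ an inverse-gamma(0.01, 0.01).
Categorical covariates are dummy-coded against their first (categorical-order
or first-observed) level.  A covariate with no observed values in the data at
hand — e.g. the wealth quintile in a survey year where it was never collected
— is dropped from the design and reported as NA; in joint multi-year fits its
dummies are zeroed on the affected rows, so those records simply contribute
no information about it.  First-born children have no PBI; they enter through
a `firstborn` indicator and a zero row in the PBI smooth.

### Inference

The reference engine is a Gibbs sampler using the normal–exponential mixture
of the AL: with θ = (1−2τ)/(τ(1−τ)) and κ² = 2/(τ(1−τ)),

    y_i | v_i ~ N(η_i + θ v_i, κ² σ v_i),   v_i ~ Exp(mean σ).

Full conditionals are conjugate: the latent exponential scales are
generalised-inverse-Gaussian (sampled as reciprocal Wald variates), the whole
latent field is jointly Gaussian (one sparse normal equation and Cholesky
solve per sweep), precisions are gamma, σ is inverse-gamma, and ρ gets a
logit-scale Metropolis step using the precomputed eigenvalues of
D^(−1/2)AD^(−1/2) for the determinant.  Defaults: 6 000 iterations, 1 000
burn-in, thin 1 (all overridable); simulation studies in this repository use
shorter chains (stated per study below) after checking that their results are
stable under longer ones.

Intrinsic blocks (RW1/RW2/ICAR) are rank-deficient.  Inside the sampler each
constrained block's *constant* direction receives a unit jitter (1/n_b on the
block) so the joint posterior precision is positive definite; the draw is then
corrected by conditioning by kriging onto {Σ x_b = 0}.  Because the jittered
directions are exactly the constrained ones, the constrained target
distribution is unaffected — the jitter is exact, not approximate.  The
standalone GMRF sampler uses the same construction with a 10⁻⁸ jitter on the
full null space, and its constrained covariance equals the Moore–Penrose
pseudo-inverse of the scaled structure matrix (verified against 50 000-draw
empirical covariances).

### Calibrated credible intervals

The AL is a *working* likelihood: its posterior spread is not a consistent
estimate of the sampling variability of quantile estimates, and in the upper
tail the raw intervals are severely anticonservative (for Gaussian residuals
the raw posterior variance is ≈ (f²/τ(1−τ))² times the correct one — about a
tenth at τ = 0.92).  The engine therefore applies the standard sandwich
adjustment to the posterior covariance of the latent field,

    Σ_adj = τ(1−τ)/σ̂² · Σ̂ (A'A) Σ̂,

rescaling each coordinate's posterior deviations by √(Σ_adj,ii/Σ̂,ii)
(never below 1), re-imposing the sum-to-zero constraints, and recomputing the
stored linear-predictor and pointwise-likelihood draws from the adjusted
field so all bookkeeping stays internally consistent.  The adjustment
preserves posterior means; it only calibrates interval widths.  It is on by
default (`MCMCSettings.variance_adjust`) and is switched off where the raw
working posterior itself is the object of interest (the model-comparison
criteria, the Laplace cross-check).  In the recovery study below the adjusted
intervals achieve ~95% empirical coverage, mildly conservative.

### Laplace cross-check

`laplace_hyper_posterior` is a deliberately simplified single-grid analogue
of integrated nested Laplace approximation: for each hyperparameter value on
a user grid it finds the conditional mode of the latent field (L-BFGS on the
log joint with the check-loss kink Huberised over a half-width of 10⁻³,
configurable), forms the Gaussian approximation there, and evaluates the
ratio π(x,ϑ,y)/π̃(x|ϑ,y) at the mode; the grid is then normalised to a
discrete posterior.  Intrinsic priors are made proper with a 10⁻⁸ null-space
jitter instead of hard constraints.  With a Gaussian likelihood the
approximation is exact, and the grid posterior matches the conjugate closed
form to < 10⁻⁴ in total variation; on a tiny AL model its σ-mode agrees with
the MCMC mode to well within 0.1 on the log scale.  Nested quadrature over
multi-dimensional hyperparameters is out of scope.

## Interval aggregation

Default weights are uniform; triangular weights peaking at τ\* are available
behind a config switch (`grid.weights: triangular`).  Credible intervals of
aggregated quantities are computed by aggregating *per posterior draw*
across the τ-fits, which are run with a common seed so draw indices align;
averaging interval endpoints has no probabilistic meaning and is not done.
Aggregates are always convex combinations, hence bounded by the per-τ
extremes, and commute with affine transformations of the inputs.

## Model-comparison criteria

All four criteria are computed from the matrix of pointwise AL log
likelihoods over retained draws: DIC (with pD = D̄ − D(posterior mean), the
deviance at the posterior-mean predictor and scale), WAIC (p_waic from the
unbiased per-observation variance), −LPML from harmonic-mean conditional
predictive ordinates, and −LML via a Laplace–Metropolis estimate on a free
parametrisation (each sum-to-zero block minus its last element;
hyperparameters on log/logit scales; a small covariance jitter guards the
log-determinant, and prior terms common to candidates of equal structure are
omitted since the criterion is used for ranking).  The harmonic-mean CPO and
the Laplace–Metropolis evidence are both known to be noisy estimators; they
are validated against exact conjugate-Gaussian leave-one-out and evidence
formulas and used for ranking only.

The selection sweep fits one candidate per row of a candidate table (age ∈
{RW1, RW2}, PBI ∈ {RW1, RW2}, spatial ∈ {ICAR, PCAR, IID}, temporal ∈
{RW1, RW2}, varied one component at a time by default), and selects by
majority vote across the four criteria with ties broken by smallest DIC.
One convolution (ICAR + IID) model is never fitted: the sweep compares one
latent spatial term at a time.

**A finding worth knowing:** DIC does *not* reliably prefer RW2 over RW1 on
data with a linear age trend when both carry the vague Gamma(1, 5·10⁻⁵)
precision prior.  The AL scale absorbs RW1's in-sample noise-chasing (a
wiggly fit shrinks Σρ_τ and hence σ̂, lowering the whole deviance), and pD
under-penalises it; the ranking becomes a coin flip with occasional large
margins for RW1.  The null-space argument for RW2 — linear trends cost it
nothing — only bites when the smoothness penalty binds.  The packaged sweep
study therefore compares the two priors at matched smoothness (an
informative Gamma(100, 0.1) precision hyperprior, concentrated near 10³);
under that design RW2 wins the DIC comparison in 10/10 replicates with
margins of 20–50 deviance units.

## The synthetic generator

There is no redistributable microdata, so the generator emulates the
*structure* of a three-round child-anthropometry survey: 13 regions on the
shipped adjacency map, survey years 2000/2006/2013, six binary covariates
(urban residence, improved water, improved toilet, television, male household
head, male child), a five-level wealth quintile (missing for every year-2000
record, as in the emulated surveys) and four-level maternal education, child
age 0–59 months, and PBI ≥ 9 months with a configurable first-born fraction
(default 0.25; PBI months are 9 + a rounded gamma(3, 12), capped at 180).

The outcome is Gaussian location-scale:

    y = μ(x) + σ(x)·ε,   μ = β₀ + x'β_loc + g_age + g_pbi + u_region + v_year,
    log σ(x) = γ₀ + x'γ_scale,

so every conditional quantile is analytic: Q_τ(y|x) = μ(x) + Φ⁻¹(τ)σ(x).
Truth curves: an inverse-U age curve peaking at 24 months (height 0.35,
half-width 30) and a monotone decreasing sigmoid PBI curve (centre 48,
scale 12, height 0.3); u is an ICAR draw (precision 4, centred) and v a
centred RW1 over years (step SD 0.15).  Default per-year sample size is
1 500 (the emulated rounds ranged from ~1 000 to ~2 400) and the intercept is
−0.4 so that, with the mean covariate/curve contribution of ≈ +0.8 z-units,
combined overweight/obesity prevalence lands in the mid single digits as in
the emulated surveys.  Default covariate prevalences are plausible
southern-African household figures chosen once (urban 0.48, improved water
0.80, improved toilet 0.45, television 0.35, male head 0.55, male child
0.51, uniform wealth quintiles, education 0.12/0.35/0.45/0.08).

One subtlety: with σ(x) = exp(·), the τ-quantile contrast of a binary dummy
is β_loc + Φ⁻¹(τ)·σ_ref·(e^γ − 1) *at reference levels of everything else*,
and with two or more scale covariates the linear quantile model is
misspecified (contrasts stop being additive).  `true_fixed_effect` implements
the exact single-dummy contrast, and the recovery study places a scale effect
on a single covariate (urban) so the analytic weighted truth
Σⱼ ωⱼ β(τⱼ) is exact for every fitted coefficient.

What the generator does **not** emulate: survey design weights and cluster
sampling, measurement error and implausible-value flagging, informative
missingness beyond the wholly-missing-wealth pattern, non-Gaussian outcome
tails, and regional sample-size imbalance.  Passing tests therefore certify
the estimator's internal correctness and calibration under a known
location-scale truth, not its behaviour under real survey artefacts.

## Simulation-study problem sizes

Chosen so the full suite and the acceptance script each finish in minutes on
one core, after checking stability at larger sizes:

* recovery: 3 × 667 ≈ 2 000 records, grid {0.85, 0.92, 0.99}, 20 replicates,
  chains 1 400/400 burn-in; coverage counted over 4 coefficients × 20 seeds.
* tail-quantile oracle: n = 5 000, chains 2 500/500.
* GMRF sampler: RW1 n = 4, 50 000 draws, entrywise 3-MC-SE band.
* conjugate criteria: n = 500 observations, 20 000 exact posterior draws.
* Laplace: n = 50; 22-point precision grid (Gaussian), 40-point log-spaced
  σ grid and a 21 000-draw chain (AL comparison).
* sweep: n = 400, 10 replicates, chains 2 000/500.
* smoke/determinism: n = 501, three τ levels, chains 600/200.

## Numerical choices and degenerate inputs

* GIG draws use the reciprocal-Wald identity with the χ parameter floored at
  10⁻¹² (residuals exactly at the fitted quantile).
* The empirical check-loss minimiser (test oracle) uses bounded scalar
  minimisation to 10⁻¹⁰; ties among empirical quantiles resolve inside the
  flat region, within the tolerance of every comparison that uses it.
* Grid construction requires the interval to sit strictly inside (0, 1) and
  the step to divide the width; Δτ\* = 0 short-circuits to a single level.
* `normalize_weights` rejects negatives and all-zero input; sums are exact to
  10⁻¹² (floating-point division only).
* Prevalence percentages round half-up to one decimal (`decimal`-based), the
  display convention of survey reports; BMIAZ = 3 is classified overweight
  (the published cut-offs "2 ≤ z ≤ 3" and "z > 3" leave no other consistent
  choice); BMIAZ = 2 is overweight (inclusive lower bound).
* A temporal term requested on single-year data is silently omitted (no
  contrast exists).
* ESS is estimated by the initial-positive-sequence rule on scalar chains.

## Known limitations

* Full INLA machinery (CCD/grid integration over multi-dimensional ϑ,
  simplified/full Laplace marginal corrections) is out of scope; the grid
  Laplace routine handles one hyperparameter at a time well.
* Quantile crossing is not corrected: per-τ fits are independent and extreme
  configurations can yield crossing fitted quantiles; interval aggregation
  averages over levels and is less exposed, but no guarantee is made.
* The harmonic-mean CPO estimator has heavy-tailed error for influential
  observations; −LML via Laplace–Metropolis assumes near-Gaussian posteriors.
* Survey years are modelled as a unit-step random walk over the *ordered*
  surveys; the unequal calendar gaps (6 and 7 years) are not rescaled.
* Per-year fitting is available by filtering the data to one year (the
  temporal term then drops automatically); the joint fit shares covariate
  effects across years.
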