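# qintreg

Bayesian spatio-temporal **quantile-interval regression** for child
overnutrition surveillance.

Childhood overweight and obesity are defined on the BMI-for-age z-score
(BMIAZ) scale: overweight is 2 ≤ BMIAZ ≤ 3, obesity BMIAZ > 3 (2006 WHO
growth standard).  Modelling the *mean* z-score says little about these
children; what matters is how covariates shift the upper tail of the
conditional BMIAZ distribution.  `qintreg` fits Bayesian structured additive
quantile regressions at a grid of upper-tail levels and combines them into
quantile-interval weighted estimates

    β̂ᵢ(τ*±Δτ*) = Σⱼ ωⱼ β̂ᵢⱼ(τⱼ),    ĝᵢ(τ*±Δτ*) = Σⱼ ωⱼ ĝᵢⱼ(τⱼ),   Σⱼ ωⱼ = 1,

with the overweight convention τ\* = 0.92, Δτ\* = 0.07 — the interval
[0.85, 0.99].  Each per-τ model is a latent Gaussian hierarchy with an
asymmetric-Laplace working likelihood: dummy-coded household/child
covariates, random-walk (RW1/RW2) smooths for child age and preceding birth
interval, an ICAR/PCAR/IID spatial effect on a region adjacency graph, and a
random-walk effect over survey years.  Inference is a conjugate Gibbs sampler
(normal–exponential mixture of the AL) with sandwich-calibrated credible
intervals, plus a simplified Laplace grid approximation of hyperparameter
posteriors as a cross-check.  Candidate latent models and priors are ranked
by DIC, WAIC, −LPML (from CPO) and −LML.

It is aimed at biostatisticians and epidemiologists analysing DHS-style
child-level survey tables (which are access-restricted); a seeded synthetic
generator with analytically known conditional quantiles stands in for such
data and backs every test.

## Worked example

```python
import qintreg as q

graph = q.build_region_graph("namibia13")          # 13-region adjacency
data  = q.generate_dataset(q.GeneratorConfig(n_per_year=800, seed=1), graph)

print(q.prevalence_table(data).to_string(index=False))

grid = q.make_quantile_grid(0.92, 0.07, step=0.07)   # {0.85, 0.92, 0.99}
spec = lambda t: q.ModelSpec(
    tau=t,
    fixed_covariates=("urban", "television", "male_child"),
    smooth_terms={"child_age_months": "RW2"},
    spatial_term=q.LatentSpec("ICAR", graph=graph),
    temporal_term="RW1",
)
mcmc = q.MCMCSettings(iterations=2000, burn_in=500)
fits = {t: q.fit_quantile_model(data, spec(t), mcmc, seed=1)
        for t in grid.points}

agg = q.aggregate_draws({t: f.fixed_draws for t, f in fits.items()}, grid)
import numpy as np
for j, lab in enumerate(fits[0.92].fixed_labels):
    lo, hi = np.quantile(agg[:, j], [0.025, 0.975])
    print(f"{lab:12s} {agg[:, j].mean():6.3f}  [{lo:6.3f}, {hi:6.3f}]")
```

prints (here: prevalence of the synthetic cohort, then the aggregated
interval coefficients with 95% credible intervals):

```
 year  total  overweight  overweight_pct  obese  obese_pct  combined_pct
 2000    800          46             5.8      8        1.0           6.8
 2006    800          44             5.5     10        1.3           6.8
 2013    800          49             6.1     12        1.5           7.6
(Intercept)   1.816  [ 1.509,  2.206]
urban         0.467  [ 0.128,  0.837]
television    0.035  [-0.544,  0.605]
male_child   -0.011  [-0.372,  0.285]
```

Each coefficient is the weighted-average shift of the [0.85, 0.99] quantile
band of BMIAZ when the dummy switches on — e.g. urban residence raises the
upper-tail z-score band by ≈ 0.5 units in this synthetic cohort (its
generating truth combines a location effect and a residual-scale effect),
while the television and male-child intervals straddle zero at this sample
size.

The same workflow runs from the shell:

```sh
qintreg all --config config.yaml --seed 1 --outdir results/
```

with subcommands `simulate`, `fit`, `aggregate`, `criteria`, `report`, `all`,
writing prevalence, per-τ posterior summaries, interval-aggregated
coefficient/curve tables, region-significance codes (−1/0/+1) and a
criteria table to the output directory.

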