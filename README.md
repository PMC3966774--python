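# refuge-dynamics

Predator–prey analysis of a two-zone wolf–elk system in which one zone
is a predation refuge: elk around a townsite are effectively safe from
wolves, while elk in the adjacent valley are the wolves' primary prey.
The package asks whether the refuge couples to the valley's dynamics
through source–sink movements, by fitting five nested continuous-time
models to 26 winters of annual counts and ranking them by
information-theoretic support.

Intended users: quantitative ecologists and biostatisticians fitting
small ODE population models to short count time series with Bayesian
MCMC.

## The models and the method

State variables: refuge elk `E`, valley elk `N`, valley wolves `P`.
The null structure is

    dE/dt = g E (1 − E/K) − s E·1[t ∈ relocation window]
    dN/dt = r N − d N P
    dP/dt = c d N P − x P

and the four alternatives add, respectively: refuge→valley dispersal
`m E` (before the management window only); valley→refuge risk-avoidance
movement `f N (1 − E/K) H(K − E)`; both; or direct wolf predation on
refuge elk at a second encounter rate `d1`. All models share the
relocation term `−sE` during a four-winter management window in which
a fraction `s` of refuge elk per year was removed from the system.

Fitting is a two-step procedure: a bounded nonlinear least-squares fit
of the mean-scaled counts (all three series given equal weight)
initialises a Delayed Rejection Adaptive Metropolis (DRAM) chain —
110,000 draws, 10,000 burn-in, covariance adaptation every 1,000
iterations, up to three delayed-rejection stages — under uniform box
priors (`s ≤ 1`, `K ≤ 3000`) and a Gaussian likelihood with conjugately
sampled error variance. Models are compared by

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n − k − 1),

with RSS evaluated at the posterior median, n = 78 observations and
k = 10, 11, 11, 12, 11 parameters, and by the Akaike weights
`w_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2)`.

The real monitoring series is not publicly archived, so a first-class
synthetic generator (`refuge_dynamics.synthetic`) reproduces its
statistical structure — 26 annual counts per series, the relocation
window, pack-summation and 13% sightability conventions, proportional
survey noise — and every pipeline stage is validated against it.
See `docs/methods.md` for the full model description, priors,
numerical choices and known limitations.

## Worked example

```python
import numpy as np
from dataclasses import replace
import refuge_dynamics as rd

# a synthetic 26-winter series from the null model at the published medians
scenario = replace(rd.scenario_presets()["model1_median"], rng_seed=11)
counts = rd.generate(scenario)

# fit the null and wolf-spillover structures with the reduced profile
cfg = rd.SamplerConfig(**rd.FAST_PROFILE, seed=11)
result = rd.run_analysis(rd.RunConfig(counts="model1_median", models=(1, 5),
                                      sampler=cfg, seed=11))
print(result.fits[1].summary.loc[["g", "K", "d"]].round(3))
print(result.table[["rss", "k", "aicc", "delta_aicc", "weight"]].round(3))
```

prints (posterior summaries for the null model, then the selection table):

           mean    median  ci_lower  ci_upper
    g     0.049     0.045     0.026     0.087
    K  1387.776  1246.241   591.021  2886.069
    d     0.020     0.020     0.018     0.023

                 rss   k     aicc  delta_aicc  weight
    model
    1      11580.604  10  413.313       0.000   0.863
    5      11724.175  11  416.991       3.677   0.137

The generating values (g = 0.08, K = 630, d = 0.02) all sit inside
their 95% credibility intervals — the encounter rate tightly, growth
rate and capacity with the wide, right-skewed uncertainty typical of a
26-point series under 10% survey noise — and the generating structure
takes ~86% of the Akaike weight against the spillover alternative: the
data contain no evidence for wolf predation inside the refuge, which
is exactly how they were built.

The same pipeline runs from a shell:

    refuge-dynamics simulate --preset model1_median --seed 11 --out counts.csv
    refuge-dynamics run --counts counts.csv --fast --seed 11 --out results/

Short narrative scripts, one per capability, live in `examples/`.

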