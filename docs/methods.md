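# Methods

## The system and the models

Three populations are tracked on an annual winter grid: elk occupying a
predation refuge around a townsite (`E`), elk in the adjacent valley
(`N`), and the valley wolf pack (`P`). Wolves avoid the townsite, so the
refuge herd experiences essentially no predation, while valley elk are
the wolves' primary prey. Five nested continuous-time structures encode
competing hypotheses about movement between the two zones:

1. **Null** — no exchange. Refuge elk grow logistically,
   `dE/dt = gE(1 − E/K)`; the valley pair follows Lotka–Volterra,
   `dN/dt = rN − dNP`, `dP/dt = cdNP − xP`.
2. **Density-dependent dispersal** — a flux `mE` moves refuge elk into
   the valley, active only before the management window (relocation
   removed the crowding that motivates dispersal, so the term is kept
   off from the window onward — permanently, the simplest reading of
   the design).
3. **Predation-risk avoidance** — a flux `fN(1 − E/K)·H(K − E)` moves
   valley elk into the refuge, shrinking as the refuge fills and gated
   to zero above carrying capacity by the Heaviside step `H` (right
   continuous: `H(0) = 1`).
4. **Both** fluxes, with independent rates.
5. **Wolf spillover** — wolves also encounter refuge elk, at a second
   rate `d1` (the valley rate is then conventionally written `d2`; the
   field keeps the name `d`), adding `−d1·E·P` to the refuge equation
   and `c(d1 E + d N)P` to wolf growth.

All five include a relocation term `−sE` during the four-winter
management window (years 13–16 of the series, half-open interval
[13, 17)): a fraction `s` of refuge elk was removed from the system per
year. The window is embedded in the differential equation as a
continuous removal, not a discrete cull. The management record calls
the program both "1998 to 2001" and a three-year period; this package
reads it as the four winters starting in year 13, fixed in
`ManagementSchedule` and configurable.

Parameter counts per structure are 10 / 11 / 11 / 12 / 11 (growth,
capacity, interaction and mortality rates plus the three initial
populations, and the structure-specific movement rates).

## Data conventions

Counts are one row per winter: refuge elk, valley elk, valley wolves.
Two survey conventions are provided as explicit operations: early-period
wolf counts are the sum of two packs (`merge_pack_counts`), and aerial
elk counts carry a 13% sightability correction for observer
undercounting, implemented multiplicatively (`adjusted = raw × 1.13`).
The direction/form of that correction is not uniquely determined by the
phrase "adjustment of 13%"; the multiplicative upward form is the
simplest reading and is inverted exactly by `invert_sightability`.
Wolf counts are never adjusted. Adjusted counts may be fractional and
are treated as continuous observations; missing winters are rejected.

## Fitting

**Scaling.** Each series is divided by (series mean / grand mean of the
three series means), so all three scaled series share the same mean and
carry equal weight in the objective while preserving overall magnitude.
The exact transform behind the original analysis is not recoverable
without the raw counts; this convention is the package's choice, and any
arithmetic on published residual sums of squares takes those values as
given inputs.

**Least squares.** A bounded trust-region least-squares fit
(`scipy.optimize.least_squares`, trf, numerical Jacobian, at most 500
evaluations, `ftol` 1e−8) of the scaled residual vector initialises the
sampler; its residual variance `ss/(n − k)` seeds the error variance.

**Likelihood and priors.** Observation error is iid Gaussian on the
scaled counts with a shared variance σ²; parameters carry uniform box
priors. Stated bounds: `s ≤ 1` (no more than the whole refuge herd
removable per year) and `K ≤ 3000`; movement/differential-predation
rates (`m`, `f`, `d1`) have inclusive-zero lower bounds, all other
parameters exclusive-zero (implemented as 1e−6). The remaining upper
bounds are plausibility choices, wide relative to every reported
credibility interval: growth rates ≤ 1/yr, `d`, `d1` ≤ 0.5 per wolf
per year, `c` ≤ 1, `x` ≤ 2/yr, initial elk ≤ 3000, initial wolves
≤ 100, `m` ≤ 1, `f` ≤ 2. σ² is treated as estimated: it carries a weak
inverse-gamma prior (shape 0.01, scale 0.01·σ̂²_LSQ) and is refreshed
each iteration from its conjugate full conditional. Counting σ² as one
estimated parameter is exactly what the published selection-table
arithmetic implies (see below).

**DRAM.** Delayed Rejection Adaptive Metropolis with the standard
recipe: 110,000 draws, 10,000 burn-in, proposal covariance re-adapted
every 1,000 iterations to `(2.4²/k)(cov(history) + 1e−10 I)`, up to
three proposal stages per iteration with the covariance shrunk by a
factor 3 per extra stage (the shrink factor is a toolbox convention;
the source analysis does not state one). The initial proposal is
diagonal at 5% of |θ₀| per axis (floored at 1e−4 of the box width so
parameters starting at zero can move). Acceptance at stages 2–3 uses
the reversibility-preserving delayed-rejection recursion; a zero
denominator yields acceptance 0. One seeded generator drives all
randomness, so chains are bitwise reproducible. A reduced profile
(20,000/2,000) serves tests and quick exploration.

## Model selection

Models are ranked by `AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n − k − 1)`
with RSS evaluated at the componentwise posterior median (not the best
visited sample), `n = 78` (26 winters × 3 series) and
`k ∈ {10, 11, 11, 12, 11}`. Neither `n` nor `k` is stated alongside the
published table; a brute-force scan over `n ∈ [20, 200]` and per-model
`k ∈ [5, 20]` (`design_scan`) shows this is the *unique* configuration
reproducing all five published AICc values to ±0.01 — consistent with
each model's fitted dynamical parameters plus one error-variance term.
Akaike weights `w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)` are computed from
unrounded AICc values; rounding ΔAICc first would shift the top weight
from 0.629 to 0.630.

## Numerics

The solver is a fixed-step classical RK4 sweep between hard breakpoints
placed at every observation time and window edge, so the discontinuous
relocation/dispersal forcing never crosses a step. Default sub-step
0.02 yr; halving it changes observed-time values by ~1e−10 relative,
comfortably inside the 1e−6 contract asserted in tests, and closed-form
checks (logistic growth; the Lotka–Volterra first integral
`Q = cdN − x ln N + dP − r ln P` at `g = 0`) hold to 1e−13 / 1e−12.
States are clamped into [0, 1e9]: small negative undershoots truncate
at zero, and hitting the upper cap flags the trajectory as diverged, in
which case the objective returns +∞ and optimiser/sampler reject the
point. This matters because the prior box contains corners where a
fixed-step scheme is unstable; such corners carry essentially no
posterior mass, and rejecting them is the intended behaviour. The inner
loop is JIT-compiled with numba, with a pure-Python fallback when numba
is unavailable. The replicated simulation experiments in the acceptance
suite use sub-step 0.05 yr (halved-step error ~5e−9) and the reduced
sampler profile — 20 replicates × 20,000-draw chains — as the package's
reduced-experiment sizes.

## Synthetic data

The monitoring series behind the original analysis is not publicly
archived, so the generator stands in for it: a deterministic trajectory
from one of the five structures on a 26-winter grid, observed through
multiplicative noise. Default noise is proportional-normal
(sd = CV × predicted value, truncated at zero; CV defaults to 0.10, a
conventional aerial-survey figure — the true survey error is unknown),
with a lognormal alternative. Optional raw-count emulation deflates elk
by the sightability factor, rounds, and re-adjusts; rounding to integer
census counts happens after noise. Wolf counts are never
sightability-adjusted. Presets parameterise each structure at the
published posterior medians (e.g. null model: g = 0.08, K = 630,
E₀ = 335, s = 0.52, r = 0.03, d = 0.02, c = 0.07, x = 0.23, N₀ = 438,
W₀ = 7; spillover model adds d1 = 0.0007), plus a high-noise variant
for power checks.

**What passing on synthetic data does and does not show.** The
generator reproduces the deterministic skeleton and a plausible
observation process, not demographic (birth-pulse) stochasticity,
process noise, or spatially explicit movement. One mismatch is
deliberate and consequential: the generator's proportional noise is
heteroscedastic, while the likelihood assumes one shared variance on
the scaled counts. Parameters pinned by the largest counts — most
visibly the valley elk initial population N₀, whose early counts are
the largest and noisiest in the series — therefore get
anti-conservative credibility intervals: in the 20-replicate recovery
experiment at CV = 0.05, N₀ falls inside its 95% interval in well under
90% of replicates (and x, c, W₀ sit marginally below that bar), while
the remaining parameters cover at or near nominal. This is a property
of the noise/likelihood pair, not of the sampler, which matches a
conjugate Gaussian posterior to Monte-Carlo error on an analytic
target. Real-data credibility intervals inherit the same caveat to the
extent real survey error is proportional.

## Known limitations

* Single chain per model with visual/split diagnostics in the report
  bundle; no multi-chain convergence statistic is enforced.
* No global-optimisation guarantee for the least-squares initialiser;
  the sampler provides the robustness.
* Discrete-time formulations, alternative functional responses and
  time-lagged dynamics are out of scope by design.
* The dispersal term stays off after the management window ends;
  whether it should resume is undefined in the source design and the
  literal reading is kept.
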