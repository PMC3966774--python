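"""Rank all five model structures on one synthetic series.

Data are generated from the null model with the default 10% survey
noise.  On any single noisy realization the extra movement terms of an
alternative structure can soak up enough noise to win the table - that
is what happens on this seed, where the risk-avoidance structure takes
the top Akaike weight.  Replicated at lower noise, the generating
structure wins the table most of the time (the acceptance suite runs
that experiment: 20 replicates at CV = 0.05).
"""

from refuge_dynamics import FAST_PROFILE, RunConfig, SamplerConfig, run_analysis

result = run_analysis(RunConfig(
    counts="model1_median",
    models=(1, 2, 3, 4, 5),
    sampler=SamplerConfig(**FAST_PROFILE, seed=3),
    seed=3,
    dt=0.05,
))

print(result.table[["rss", "k", "aicc", "delta_aicc", "weight"]]
      .round(3).to_string())
best = int(result.table["weight"].idxmax())
print(f"\nRSS is the scaled sum of squares at each posterior median; "
      f"AICc penalises the extra movement parameters (k = 10..12). "
      f"On this realization model {best} carries "
      f"{result.table.loc[best, 'weight']:.0%} of the Akaike weight"
      + (" - the generating (null) structure wins."
         if best == 1 else
         " - a movement structure beats the generating null model on "
         "this draw, a reminder that single noisy series can favour "
         "overparameterised dynamics."))
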