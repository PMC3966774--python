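"""Synthetic count series with the statistical structure the analysis
assumes.

The real 26-winter monitoring series is not publicly archived, so every
pipeline stage is exercised against generated data: a deterministic ODE
trajectory from one of the five model structures, observed through
multiplicative survey noise (proportional-normal by default, lognormal as
an alternative), optionally pushed through the raw-count conventions
(inverse sightability adjustment then re-adjustment for the elk series,
integer rounding after noise).

Presets parameterised at the published posterior medians give scenarios
whose trajectory shapes mirror the study system: refuge elk rise toward
carrying capacity, crash under the four-winter relocation program, then
regrow; valley elk decline while wolves rise and fall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import ManagementSchedule, ModelSpec, ParamVector, Trajectory, integrate
from .timeseries import CountSeries, apply_sightability, invert_sightability

__all__ = ["SyntheticScenario", "simulate_truth", "observe", "generate",
           "scenario_presets"]

_NOISE_MODELS = ("proportional-normal", "lognormal")


@dataclass(frozen=True)
class SyntheticScenario:
    """Generating configuration for one synthetic series.

    ``noise_scale`` is the coefficient of variation of the observation
    noise (default 0.10, a conventional aerial-survey figure; the true
    survey error is unknown).  ``apply_sightability_cycle`` mimics raw
    elk counts: predicted elk are deflated by the sightability factor,
    optionally rounded, then re-adjusted, as the survey pipeline would.
    """

    model_id: int
    theta_true: ParamVector
    schedule: ManagementSchedule = field(default_factory=ManagementSchedule)
    n_years: int = 26
    noise_model: str = "proportional-normal"
    noise_scale: float = 0.10
    round_to_integers: bool = False
    apply_sightability_cycle: bool = False
    sightability_rate: float = 0.13
    first_winter: int = 1985
    rng_seed: int = 0

    def __post_init__(self):
        if self.noise_model not in _NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {_NOISE_MODELS}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.n_years < 3:
            raise ValueError("need n_years >= 3")

    @property
    def model(self) -> ModelSpec:
        return ModelSpec(self.model_id, self.schedule)


def simulate_truth(scenario: SyntheticScenario, dt: float = 0.02) -> Trajectory:
    """Deterministic trajectory on the annual grid (thin delegation to the
    model integrator)."""
    traj = integrate(
        scenario.model, scenario.theta_true,
        horizon=float(scenario.n_years - 1),
        obs_times=np.arange(scenario.n_years, dtype=float), dt=dt,
    )
    if traj.diverged:
        raise RuntimeError("scenario trajectory diverged; check theta_true")
    return traj


def observe(trajectory: Trajectory, scenario: SyntheticScenario,
            rng=None) -> CountSeries:
    """Draw one noisy observation of a trajectory.

    Noise is applied per point with the scenario's coefficient of
    variation (sd = CV * predicted value for proportional-normal; for
    lognormal, the log-sd is chosen so the draw's CV matches).  Negative
    draws truncate at zero; rounding, when enabled, happens after noise,
    mimicking census counts.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.rng_seed)
    vals = trajectory.stacked().copy()
    cv = scenario.noise_scale
    if cv > 0:
        if scenario.noise_model == "proportional-normal":
            vals = vals + rng.standard_normal(vals.shape) * cv * vals
        else:
            sd = np.sqrt(np.log1p(cv * cv))
            vals = vals * np.exp(rng.standard_normal(vals.shape) * sd
                                 - 0.5 * sd * sd)
        vals = np.maximum(vals, 0.0)
    if scenario.apply_sightability_cycle:
        for col in (0, 1):  # elk series only; wolves are never adjusted
            raw = invert_sightability(vals[:, col], scenario.sightability_rate)
            if scenario.round_to_integers:
                raw = np.round(raw)
            vals[:, col] = apply_sightability(raw, scenario.sightability_rate)
        if scenario.round_to_integers:
            vals[:, 2] = np.round(vals[:, 2])
    elif scenario.round_to_integers:
        vals = np.round(vals)
    years = scenario.first_winter + np.arange(scenario.n_years)
    return CountSeries(
        winter_start_year=years,
        banff_elk=vals[:, 0], bow_elk=vals[:, 1], bow_wolves=vals[:, 2],
    )


def generate(scenario: SyntheticScenario, rng=None, dt: float = 0.02) -> CountSeries:
    """simulate_truth followed by observe, in one call."""
    return observe(simulate_truth(scenario, dt), scenario, rng)


def scenario_presets() -> dict[str, SyntheticScenario]:
    """Named scenarios at the published posterior medians, one per model
    structure, plus a high-noise null-recovery variant for power checks."""
    base = dict(
        g=0.08, K=630.0, E0=335.0, s=0.52, r=0.03, d=0.02, c=0.07, x=0.23,
        N0=438.0, W0=7.0,
    )
    presets = {
        "model1_median": SyntheticScenario(1, ParamVector(**base)),
        "model2_median": SyntheticScenario(2, ParamVector(**{
            **base, "g": 0.07, "K": 677.0, "E0": 340.0, "s": 0.51,
            "N0": 442.0, "W0": 6.0, "m": 0.01})),
        "model3_median": SyntheticScenario(3, ParamVector(**{
            **base, "g": 0.05, "K": 513.0, "E0": 298.0, "s": 0.56,
            "f": 0.19})),
        "model4_median": SyntheticScenario(4, ParamVector(**{
            **base, "g": 0.04, "K": 520.0, "E0": 300.0, "s": 0.56,
            "c": 0.06, "N0": 443.0, "W0": 6.0, "m": 0.01, "f": 0.18})),
        "model5_median": SyntheticScenario(5, ParamVector(**{
            **base, "g": 0.07, "K": 1039.0, "E0": 340.0, "r": 0.04,
            "x": 0.25, "N0": 440.0, "d1": 0.0007})),
        "model1_noisy": SyntheticScenario(1, ParamVector(**base),
                                          noise_scale=0.25),
    }
    return presets
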