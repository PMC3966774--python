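"""Scaled least-squares objective and the nonlinear least-squares fit.

The three count series live on very different scales (hundreds of elk,
a handful of wolves).  Before computing residuals every series is divided
by its own mean and re-multiplied by the grand mean of the three series
means, so all three scaled series share the same mean and therefore
receive equal weight in the sum of squares, while the overall magnitude
of the data is preserved.

The least-squares fit is a bounded trust-region minimisation of the
scaled residual vector; its solution seeds the MCMC sampler and provides
the residual-variance estimate used to initialise the error variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .models import (DEFAULT_BOUNDS, PARAM_ORDER, IntegrationPlan, ModelSpec,
                     ParamVector, integrate)
from .timeseries import CountSeries

__all__ = [
    "scale_series",
    "ScaledObjective",
    "evaluate",
    "sum_of_squares",
    "make_objective",
    "FitResult",
    "least_squares_fit",
]

_SS_FAIL = np.inf


def scale_series(counts: CountSeries) -> np.ndarray:
    """Per-series scale factors: factor_k = mean_k / grand_mean.

    Dividing series k by factor_k gives every scaled series the same mean
    (the grand mean of the three series means), equalising their weight
    in the objective.
    """
    means = counts.stacked().mean(axis=0)
    if np.any(means == 0):
        k = int(np.flatnonzero(means == 0)[0])
        raise ValueError(f"series {k} has zero mean; cannot scale")
    return means / means.mean()


@dataclass(frozen=True)
class ScaledObjective:
    """One evaluation of the scaled objective."""

    scale_factors: np.ndarray
    residual_vector: np.ndarray
    ss: float


def _theta_from_active(model: ModelSpec, active: np.ndarray) -> ParamVector:
    kw = dict(zip(model.active_params, map(float, active)))
    return ParamVector(**{k: v for k, v in kw.items()})


class _ActivePacker:
    """Maps active-parameter arrays into the canonical 13-slot layout with
    the container's validity checks, avoiding dataclass overhead in hot
    loops (returns None for an invalid point)."""

    def __init__(self, model: ModelSpec):
        self._idx = np.array([PARAM_ORDER.index(p) for p in model.active_params])
        self._template = np.zeros(len(PARAM_ORDER))
        self._pop = np.array([PARAM_ORDER.index(p)
                              for p in ("K", "E0", "N0", "W0")])
        self._s = PARAM_ORDER.index("s")
        self._K = PARAM_ORDER.index("K")

    def pack(self, active) -> np.ndarray | None:
        p = self._template.copy()
        p[self._idx] = active
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            return None
        if np.any(p[self._pop] <= 0):
            return None
        if p[self._s] > 1.0 or p[self._K] > 3000.0:
            return None
        return p


def _residuals(theta: ParamVector, model: ModelSpec, counts: CountSeries,
               factors: np.ndarray, dt: float) -> np.ndarray | None:
    traj = integrate(
        model, theta, horizon=float(counts.n_years - 1),
        obs_times=counts.t_index.astype(float), dt=dt,
    )
    if traj.diverged:
        return None
    return ((counts.stacked() - traj.stacked()) / factors).ravel()


def evaluate(theta: ParamVector, model: ModelSpec, counts: CountSeries,
             factors=None, dt: float = 0.02) -> ScaledObjective:
    """Integrate the model and return scaled residuals and their sum of
    squares; a diverged trajectory yields an infinite objective."""
    if factors is None:
        factors = scale_series(counts)
    factors = np.asarray(factors, dtype=float)
    res = _residuals(theta, model, counts, factors, dt)
    if res is None:
        return ScaledObjective(factors, np.full(counts.n_obs, np.nan), _SS_FAIL)
    return ScaledObjective(factors, res, float(res @ res))


def sum_of_squares(theta: ParamVector, model: ModelSpec, counts: CountSeries,
                   factors=None, dt: float = 0.02) -> float:
    return evaluate(theta, model, counts, factors, dt).ss


def make_objective(model: ModelSpec, counts: CountSeries, factors=None,
                   dt: float = 0.02):
    """Closure mapping an active-parameter array to the scaled sum of
    squares (infinite when integration diverges or parameters are
    invalid); used by the MCMC sampler."""
    if factors is None:
        factors = scale_series(counts)
    factors = np.asarray(factors, dtype=float)
    obs = counts.stacked()
    plan = IntegrationPlan(model, float(counts.n_years - 1),
                           counts.t_index.astype(float), dt)
    packer = _ActivePacker(model)

    def ss(active: np.ndarray) -> float:
        p = packer.pack(active)
        if p is None:
            return _SS_FAIL
        pred, diverged = plan.states(p)
        if diverged:
            return _SS_FAIL
        r = ((obs - pred) / factors).ravel()
        return float(r @ r)

    return ss


@dataclass(frozen=True)
class FitResult:
    theta_hat: ParamVector
    ss: float
    sigma2_hat: float
    converged: bool
    message: str
    n_evaluations: int


def least_squares_fit(model: ModelSpec, counts: CountSeries,
                      theta0: ParamVector, bounds: dict | None = None,
                      dt: float = 0.02, max_nfev: int = 500) -> FitResult:
    """Bounded trust-region least squares on the scaled residual vector.

    Returns the best point found even on non-convergence (flagged in
    ``converged``/``message``); ``sigma2_hat = ss / (n - k)`` with k the
    number of fitted parameters, used to seed the sampler's error
    variance.
    """
    b = DEFAULT_BOUNDS if bounds is None else bounds
    lo = np.array([b[p][0] for p in model.active_params])
    hi = np.array([b[p][1] for p in model.active_params])
    x0 = np.array([getattr(theta0, p) for p in model.active_params])
    if np.any(x0 < lo) or np.any(x0 > hi):
        bad = model.active_params[int(np.flatnonzero((x0 < lo) | (x0 > hi))[0])]
        raise ValueError(f"initial value for {bad!r} is outside its bounds")
    factors = scale_series(counts)
    obs = counts.stacked()
    plan = IntegrationPlan(model, float(counts.n_years - 1),
                           counts.t_index.astype(float), dt)
    packer = _ActivePacker(model)

    def resid(active):
        p = packer.pack(active)
        if p is None:
            return np.full(counts.n_obs, 1e6)
        pred, diverged = plan.states(p)
        if diverged:
            return np.full(counts.n_obs, 1e6)
        return ((obs - pred) / factors).ravel()

    sol = least_squares(
        resid, x0, bounds=(lo, hi), method="trf",
        ftol=1e-8, xtol=1e-10, gtol=1e-10, max_nfev=max_nfev,
    )
    theta_hat = _theta_from_active(model, sol.x)
    ss = float(2 * sol.cost)
    dof = max(counts.n_obs - model.n_params, 1)
    return FitResult(
        theta_hat=theta_hat,
        ss=ss,
        sigma2_hat=ss / dof,
        converged=bool(sol.status > 0),
        message=str(sol.message),
        n_evaluations=int(sol.nfev),
    )
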