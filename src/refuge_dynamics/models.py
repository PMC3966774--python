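"""Continuous-time predator-prey models for a two-zone wolf-elk system.

Three state variables are tracked: elk in a predation refuge around a
townsite (``E``), elk in the adjacent valley where wolves hunt (``N``), and
the valley wolf population (``P``).  Five nested model structures connect
them:

* Model 1 (null): refuge elk grow logistically toward carrying capacity
  ``K``; valley elk and wolves follow Lotka-Volterra dynamics; the two
  zones do not interact.
* Model 2: adds density-dependent dispersal ``m·E`` from refuge to valley,
  active only before the management relocation window.
* Model 3: adds anti-predator movement ``f·N·(1 − E/K)·H(K − E)`` from
  valley to refuge, gated by a Heaviside function so it shuts off once the
  refuge reaches carrying capacity.
* Model 4: both movement terms.
* Model 5: wolves additionally encounter refuge elk at a second rate
  ``d1`` (the valley rate is then read as ``d2``; the field is named ``d``
  throughout).

All models share a relocation term ``−s·E`` active during a four-winter
management window in which refuge elk were removed from the system.

Integration uses a fixed-step classical Runge-Kutta scheme with hard
breakpoints at window edges and observation times, so the discontinuous
forcing terms are handled exactly; the inner loop is JIT-compiled with
numba when available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


__all__ = [
    "PARAM_ORDER",
    "MODEL_PARAMS",
    "DEFAULT_BOUNDS",
    "ParamVector",
    "ManagementSchedule",
    "ModelSpec",
    "Trajectory",
    "heaviside",
    "rhs",
    "integrate",
    "IntegrationPlan",
]

#: Canonical parameter ordering used for packed arrays.
PARAM_ORDER = ("g", "K", "E0", "s", "r", "d", "c", "x", "N0", "W0", "m", "f", "d1")

#: Fitted parameters per model structure (summary-table column order).
MODEL_PARAMS = {
    1: ("g", "K", "E0", "s", "r", "d", "N0", "x", "c", "W0"),
    2: ("g", "K", "E0", "s", "m", "r", "d", "N0", "x", "c", "W0"),
    3: ("g", "K", "E0", "s", "r", "d", "N0", "f", "x", "c", "W0"),
    4: ("g", "K", "E0", "s", "m", "r", "d", "N0", "f", "x", "c", "W0"),
    5: ("g", "K", "E0", "s", "d1", "r", "d", "N0", "x", "c", "W0"),
}

# Uniform prior box.  The study states only two upper bounds explicitly --
# the relocation fraction s <= 1 (no more than the whole refuge herd can be
# removed in a year) and the refuge carrying capacity K <= 3000 -- plus
# inclusive-zero lower bounds for the movement/differential-predation
# parameters (m, f, d1) and exclusive-zero lower bounds for everything
# else.  Remaining upper bounds are biological-plausibility choices, wide
# relative to every reported credibility interval (see docs/methods.md).
_EPS = 1e-6
DEFAULT_BOUNDS = {
    "g": (_EPS, 1.0),
    "K": (1.0, 3000.0),
    "E0": (1.0, 3000.0),
    "s": (_EPS, 1.0),
    "r": (_EPS, 1.0),
    "d": (_EPS, 0.5),
    "c": (_EPS, 1.0),
    "x": (_EPS, 2.0),
    "N0": (1.0, 3000.0),
    "W0": (0.5, 100.0),
    "m": (0.0, 1.0),
    "f": (0.0, 2.0),
    "d1": (0.0, 0.5),
}

#: States are clamped into [0, _STATE_CAP]; hitting the cap flags divergence.
_STATE_CAP = 1e9


def heaviside(x: float) -> int:
    """Unit step: 1 for x >= 0, 0 for x < 0 (right-continuous)."""
    if not math.isfinite(x):
        raise ValueError("heaviside requires a finite argument")
    return 1 if x >= 0 else 0


@dataclass(frozen=True)
class ParamVector:
    """A point in model parameter space.

    Units: rates (g, s, r, x, m, f) are per year; encounter rates (d, d1)
    per wolf per year; c is wolves produced per encountered elk
    (dimensionless); K, E0, N0, W0 are animals.  m, f and d1 default to 0
    and are only read by the models that use them.
    """

    g: float
    K: float
    E0: float
    s: float
    r: float
    d: float
    c: float
    x: float
    N0: float
    W0: float
    m: float = 0.0
    f: float = 0.0
    d1: float = 0.0

    def __post_init__(self):
        # Populations must be positive; rate parameters may sit at 0 (the
        # uniform prior box keeps them strictly positive during fitting,
        # but exact zeros are legal states, e.g. for nested-model checks).
        for name in PARAM_ORDER:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {name!r} must be finite, got {v}")
            if name in ("K", "E0", "N0", "W0"):
                if v <= 0:
                    raise ValueError(f"parameter {name!r} must be > 0, got {v}")
            elif v < 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got {v}")
        if self.s > 1.0:
            raise ValueError(f"relocation fraction s must be <= 1, got {self.s}")
        if self.K > 3000.0:
            raise ValueError(f"carrying capacity K must be <= 3000, got {self.K}")

    def to_array(self) -> np.ndarray:
        """Pack into the canonical 13-element order (``PARAM_ORDER``)."""
        return np.array([getattr(self, k) for k in PARAM_ORDER], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ParamVector":
        return cls(**dict(zip(PARAM_ORDER, map(float, arr))))

    def replace(self, **kw) -> "ParamVector":
        return replace(self, **kw)


@dataclass(frozen=True)
class ManagementSchedule:
    """Half-open activation windows (years since first winter).

    ``relocation_window`` is the management period during which refuge elk
    were removed (default winters 13..16, i.e. four winters starting in
    year 13 of the series); ``dispersal_window`` is the period during
    which density-dependent dispersal can act (before relocation began).
    """

    relocation_window: tuple[float, float] = (13.0, 17.0)
    dispersal_window: tuple[float, float] = (0.0, 13.0)

    def __post_init__(self):
        for name, (a, b) in (
            ("relocation_window", self.relocation_window),
            ("dispersal_window", self.dispersal_window),
        ):
            if not (math.isfinite(a) and math.isfinite(b) and a < b):
                raise ValueError(f"{name} must be a finite interval [a, b) with a < b")
        r0, r1 = self.relocation_window
        d0, d1 = self.dispersal_window
        if max(r0, d0) < min(r1, d1):
            raise ValueError("relocation and dispersal windows must not overlap")

    def relocation_active(self, t: float) -> bool:
        a, b = self.relocation_window
        return a <= t < b

    def dispersal_active(self, t: float) -> bool:
        a, b = self.dispersal_window
        return a <= t < b


@dataclass(frozen=True)
class ModelSpec:
    """One of the five model structures plus its management schedule."""

    model_id: int
    schedule: ManagementSchedule = field(default_factory=ManagementSchedule)

    def __post_init__(self):
        if self.model_id not in MODEL_PARAMS:
            raise ValueError(f"model_id must be 1..5, got {self.model_id}")

    @property
    def active_params(self) -> tuple[str, ...]:
        return MODEL_PARAMS[self.model_id]

    @property
    def n_params(self) -> int:
        return len(self.active_params)

    def bounds_arrays(self, bounds: dict | None = None):
        """(lo, hi) arrays over ``active_params``."""
        b = DEFAULT_BOUNDS if bounds is None else bounds
        lo = np.array([b[p][0] for p in self.active_params])
        hi = np.array([b[p][1] for p in self.active_params])
        return lo, hi


@dataclass(frozen=True)
class Trajectory:
    """Deterministic model solution sampled on the observation grid."""

    times: np.ndarray
    E: np.ndarray
    N: np.ndarray
    P: np.ndarray
    diverged: bool = False

    def __post_init__(self):
        n = len(self.times)
        if not (len(self.E) == len(self.N) == len(self.P) == n):
            raise ValueError("trajectory arrays must share the time-grid length")

    def stacked(self) -> np.ndarray:
        """(n_times, 3) array in (E, N, P) column order."""
        return np.column_stack([self.E, self.N, self.P])


@njit(cache=True)
def _rhs_core(model_id, E, N, P, p, reloc, disp):
    """Scalar right-hand side; reloc/disp are the *active* rate values."""
    g, K, E0, s, r, d, c, x, N0, W0, m, f, d1 = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9], p[10], p[11], p[12],
    )
    logistic = g * E * (1.0 - E / K)
    avoid = 0.0
    if (model_id == 3 or model_id == 4) and (K - E) >= 0.0:
        avoid = f * N * (1.0 - E / K)
    if model_id == 5:
        dE = logistic - d1 * E * P - reloc * E
        dN = r * N - d * N * P
        dP = c * (d1 * E + d * N) * P - x * P
    else:
        dE = logistic - disp * E + avoid - reloc * E
        dN = r * N + disp * E - avoid - d * N * P
        dP = c * d * N * P - x * P
    return dE, dN, dP


@njit(cache=True)
def _integrate_core(model_id, p, grid, reloc_flags, disp_flags, n_sub):
    """RK4 between consecutive grid points; window flags constant per segment.

    Returns (states, diverged) where states is (len(grid), 3).
    """
    n = grid.shape[0]
    out = np.empty((n, 3))
    E, N, P = p[2], p[8], p[9]
    out[0, 0], out[0, 1], out[0, 2] = E, N, P
    diverged = False
    for i in range(n - 1):
        reloc = p[3] if reloc_flags[i] else 0.0
        disp = p[10] if disp_flags[i] else 0.0
        h = (grid[i + 1] - grid[i]) / n_sub
        for _ in range(n_sub):
            k1E, k1N, k1P = _rhs_core(model_id, E, N, P, p, reloc, disp)
            k2E, k2N, k2P = _rhs_core(
                model_id, E + 0.5 * h * k1E, N + 0.5 * h * k1N, P + 0.5 * h * k1P,
                p, reloc, disp)
            k3E, k3N, k3P = _rhs_core(
                model_id, E + 0.5 * h * k2E, N + 0.5 * h * k2N, P + 0.5 * h * k2P,
                p, reloc, disp)
            k4E, k4N, k4P = _rhs_core(
                model_id, E + h * k3E, N + h * k3N, P + h * k3P, p, reloc, disp)
            E = E + (h / 6.0) * (k1E + 2.0 * k2E + 2.0 * k3E + k4E)
            N = N + (h / 6.0) * (k1N + 2.0 * k2N + 2.0 * k3N + k4N)
            P = P + (h / 6.0) * (k1P + 2.0 * k2P + 2.0 * k3P + k4P)
            if not (math.isfinite(E) and math.isfinite(N) and math.isfinite(P)):
                diverged = True
                E, N, P = _STATE_CAP, _STATE_CAP, _STATE_CAP
            if E < 0.0:
                E = 0.0
            elif E > _STATE_CAP:
                E = _STATE_CAP
                diverged = True
            if N < 0.0:
                N = 0.0
            elif N > _STATE_CAP:
                N = _STATE_CAP
                diverged = True
            if P < 0.0:
                P = 0.0
            elif P > _STATE_CAP:
                P = _STATE_CAP
                diverged = True
        out[i + 1, 0], out[i + 1, 1], out[i + 1, 2] = E, N, P
    return out, diverged


def rhs(model: ModelSpec, t: float, state, theta: ParamVector):
    """Evaluate (dE/dt, dN/dt, dP/dt) for one model at time ``t``.

    The relocation term is active for t inside the relocation window;
    density-dependent dispersal (Models 2 and 4) only inside the dispersal
    window.  Raises on negative state components.
    """
    E, N, P = (float(v) for v in state)
    if E < 0 or N < 0 or P < 0:
        raise ValueError(f"state must be non-negative, got {(E, N, P)}")
    reloc = theta.s if model.schedule.relocation_active(t) else 0.0
    disp = 0.0
    if model.model_id in (2, 4) and model.schedule.dispersal_active(t):
        disp = theta.m
    return _rhs_core(model.model_id, E, N, P, theta.to_array(), reloc, disp)


def _build_grid(model: ModelSpec, obs_times: np.ndarray, horizon: float):
    """Observation times merged with window edges, plus per-segment flags."""
    edges = [0.0, float(horizon)]
    for a, b in (model.schedule.relocation_window, model.schedule.dispersal_window):
        for e in (a, b):
            if 0.0 < e < horizon:
                edges.append(float(e))
    grid = np.union1d(np.asarray(obs_times, dtype=float), np.array(edges))
    mids = 0.5 * (grid[:-1] + grid[1:])
    reloc_flags = np.array([model.schedule.relocation_active(t) for t in mids])
    disp_flags = np.array(
        [model.model_id in (2, 4) and model.schedule.dispersal_active(t) for t in mids]
    )
    return grid, reloc_flags, disp_flags


class IntegrationPlan:
    """Precomputed breakpoint grid and window flags for repeated solves.

    Building the merged grid (observation times plus window edges) costs
    more than the RK4 sweep itself, so objective functions evaluated many
    thousands of times construct a plan once and reuse it.
    """

    def __init__(self, model: ModelSpec, horizon: float = 25.0, obs_times=None,
                 dt: float = 0.02):
        if obs_times is None:
            obs_times = np.arange(int(horizon) + 1, dtype=float)
        obs_times = np.asarray(obs_times, dtype=float)
        if obs_times.min() < 0 or obs_times.max() > horizon:
            raise ValueError("obs_times must lie within [0, horizon]")
        grid, reloc_flags, disp_flags = _build_grid(model, obs_times, horizon)
        self.model_id = model.model_id
        self.obs_times = obs_times
        self.grid = grid
        self.reloc_flags = reloc_flags
        self.disp_flags = disp_flags
        self.n_sub = max(1, int(np.ceil(np.diff(grid).max() / dt)))
        self.obs_index = np.searchsorted(grid, obs_times)

    def states(self, p: np.ndarray):
        """(states at obs_times, diverged) for a packed parameter array."""
        out, diverged = _integrate_core(
            self.model_id, p, self.grid, self.reloc_flags, self.disp_flags,
            self.n_sub)
        return out[self.obs_index], diverged


def integrate(
    model: ModelSpec,
    theta: ParamVector,
    horizon: float = 25.0,
    obs_times=None,
    dt: float = 0.02,
) -> Trajectory:
    """Solve the model ODEs and sample the solution at ``obs_times``.

    Window switch points are hard integration breakpoints, so the
    discontinuous relocation/dispersal forcing is resolved exactly.  ``dt``
    is the nominal sub-step; each inter-breakpoint segment uses
    ``ceil(len/dt)`` equal RK4 steps.  A trajectory whose state escapes the
    cap (1e9 animals) or turns non-finite is returned with
    ``diverged=True`` and should be treated as an infinite-objective point.
    """
    plan = IntegrationPlan(model, horizon, obs_times, dt)
    s, diverged = plan.states(theta.to_array())
    return Trajectory(
        times=plan.obs_times, E=s[:, 0], N=s[:, 1], P=s[:, 2],
        diverged=bool(diverged),
    )
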