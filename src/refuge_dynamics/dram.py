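"""Delayed Rejection Adaptive Metropolis (DRAM) sampling.

The posterior is defined by independent Gaussian observation error on the
scaled counts with a shared variance sigma^2 and uniform box priors on the
model parameters, so the log posterior kernel at fixed sigma^2 is
``-SS(theta) / (2 sigma^2)`` inside the box and minus infinity outside.
sigma^2 itself carries a weak inverse-gamma prior and is refreshed each
iteration from its conjugate full conditional.

Two efficiency devices are combined, following the standard DRAM recipe:

* Adaptation: every ``adapt_interval`` draws the Gaussian proposal
  covariance is replaced by ``(2.4^2 / k) * (cov(chain history) + eps I)``.
* Delayed rejection: after a rejection, up to two further candidates are
  proposed from the same centre with the covariance shrunk by
  ``dr_downscale`` per extra stage, accepted with the delayed-rejection
  recursion that preserves detailed balance.

A single seeded ``numpy.random.Generator`` drives every draw, so chains
are bitwise reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SamplerConfig",
    "ChainResult",
    "log_posterior_kernel",
    "propose",
    "dr_acceptance",
    "adapt_covariance",
    "sample_error_variance",
    "run_dram",
]

_COV_EPS = 1e-10


@dataclass(frozen=True)
class SamplerConfig:
    """DRAM run settings (defaults mirror the full analysis protocol:
    110,000 draws, 10,000 burn-in, up to 3 DR stages, adaptation every
    1,000 iterations)."""

    n_samples: int = 110_000
    burn_in: int = 10_000
    max_dr_stages: int = 3
    adapt_interval: int = 1_000
    dr_downscale: float = 3.0
    initial_scale: float = 0.05
    sample_sigma2: bool = True
    sigma2: float | None = None          # fixed value when sample_sigma2=False
    prior_shape: float = 0.01
    prior_scale: float | None = None     # default 0.01 * sigma2_hat from the LSQ fit
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_samples:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_samples")
        if self.max_dr_stages not in (1, 2, 3):
            raise ValueError("max_dr_stages must be 1, 2 or 3")
        if self.adapt_interval < 1:
            raise ValueError("adapt_interval must be >= 1")
        if self.dr_downscale <= 1.0:
            raise ValueError("dr_downscale must exceed 1")
        if not self.sample_sigma2 and not (self.sigma2 and self.sigma2 > 0):
            raise ValueError("fixed sigma2 must be positive when sampling is off")


@dataclass
class ChainResult:
    """Post-burn-in samples plus acceptance bookkeeping."""

    samples: np.ndarray                 # (n_samples - burn_in, k)
    sigma2_samples: np.ndarray
    param_names: tuple[str, ...]
    acceptance_rate: float
    stage_proposals: np.ndarray         # proposals attempted per DR stage
    stage_accepts: np.ndarray           # acceptances per DR stage
    n_evaluations: int
    adaptation_count: int
    config: SamplerConfig = field(repr=False, default=None)
    warning: str | None = None

    @property
    def stage_acceptance(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.stage_proposals > 0,
                self.stage_accepts / np.maximum(self.stage_proposals, 1), np.nan,
            )

    def medians(self) -> np.ndarray:
        return np.median(self.samples, axis=0)


def log_posterior_kernel(theta, ss_value: float, sigma2: float, bounds) -> float:
    """``-SS/(2 sigma^2)`` inside the uniform prior box, -inf outside.

    The flat prior contributes only a constant inside its support, so the
    kernel is the Gaussian log likelihood up to an additive constant.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    lo, hi = bounds
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < lo) or np.any(theta > hi):
        return -math.inf
    if not math.isfinite(ss_value):
        return -math.inf
    return -ss_value / (2.0 * sigma2)


def propose(current, chol_cov, stage: int, dr_downscale: float, rng=None, z=None):
    """Gaussian candidate centred on ``current``; stage j uses the adapted
    Cholesky factor shrunk by ``dr_downscale**(j-1)``."""
    if z is None:
        z = rng.standard_normal(len(current))
    return np.asarray(current) + (chol_cov @ z) / dr_downscale ** (stage - 1)


def _log1m_exp(log_a: float) -> float:
    """log(1 - exp(log_a)) for log_a <= 0, -inf when log_a == 0."""
    if log_a >= 0.0:
        return -math.inf
    if log_a < -37.0:  # exp underflows past double precision of 1
        return 0.0
    return math.log1p(-math.exp(log_a))


class _GaussStages:
    """Unnormalised log proposal densities for the DR stage covariances.

    Stage j covariance is Sigma / gamma^(2(j-1)); the normalising
    constants cancel inside each acceptance ratio because numerator and
    denominator use the same stage's density.  Holds the precomputed
    inverse Cholesky factor of the stage-1 covariance.
    """

    def __init__(self, chol, dr_downscale, inv_chol=None):
        self._inv = np.linalg.inv(chol) if inv_chol is None else inv_chol
        self._gamma = dr_downscale

    def logq(self, stage: int, center, point) -> float:
        y = self._inv @ (point - center)
        scale = self._gamma ** (stage - 1)
        return -0.5 * float(y @ y) * scale * scale


def dr_acceptance(points, log_pis, chol, dr_downscale: float) -> float:
    """Delayed-rejection acceptance probability for the final proposal.

    ``points = [x, y1, ..., yj]`` is the proposal path (all candidates
    centred on ``x`` with stage-wise shrunken covariance) and ``log_pis``
    the matching posterior kernel values.  Stage 1 is plain Metropolis;
    stages 2 and 3 apply the reversibility-preserving recursion in which
    the reverse path's first-stage rejections are accounted for.  Guarded
    so a zero denominator (a reverse path that would surely accept early)
    yields probability 0.
    """
    la = _log_alpha(list(points), list(log_pis), _GaussStages(chol, dr_downscale))
    return math.exp(min(0.0, la))


def _log_alpha(points, log_pis, q) -> float:
    j = len(points) - 1
    lp = log_pis
    if j == 1:
        if lp[0] == -math.inf:
            return 0.0  # leaving an impossible state: always accept
        if lp[1] == -math.inf:
            return -math.inf
        return min(0.0, lp[1] - lp[0])
    if j == 2:
        x, y1, y2 = points
        if lp[2] == -math.inf:
            return -math.inf
        num = (lp[2] + q.logq(1, y2, y1)
               + _log1m_exp(_log_alpha([y2, y1], [lp[2], lp[1]], q)))
        den = (lp[0] + q.logq(1, x, y1)
               + _log1m_exp(_log_alpha([x, y1], [lp[0], lp[1]], q)))
        if den == -math.inf:
            return -math.inf if num == -math.inf else 0.0
        return min(0.0, num - den)
    if j == 3:
        x, y1, y2, y3 = points
        if lp[3] == -math.inf:
            return -math.inf
        num = (lp[3] + q.logq(1, y3, y2) + q.logq(2, y3, y1)
               + _log1m_exp(_log_alpha([y3, y2], [lp[3], lp[2]], q))
               + _log1m_exp(_log_alpha([y3, y2, y1], [lp[3], lp[2], lp[1]], q)))
        den = (lp[0] + q.logq(1, x, y1) + q.logq(2, x, y2)
               + _log1m_exp(_log_alpha([x, y1], [lp[0], lp[1]], q))
               + _log1m_exp(_log_alpha([x, y1, y2], [lp[0], lp[1], lp[2]], q)))
        if den == -math.inf:
            return -math.inf if num == -math.inf else 0.0
        return min(0.0, num - den)
    raise ValueError("delayed rejection supports at most 3 stages")


def adapt_covariance(history: np.ndarray, k: int | None = None) -> np.ndarray:
    """Scaled empirical covariance ``(2.4^2 / k) (cov + eps I)`` of the
    chain history; degenerate histories floor at ``eps I``."""
    history = np.atleast_2d(np.asarray(history, dtype=float))
    if history.shape[0] < 2:
        raise ValueError("need at least 2 history rows to adapt")
    if k is None:
        k = history.shape[1]
    cov = np.cov(history, rowvar=False)
    cov = np.atleast_2d(cov)
    return (2.4 ** 2 / k) * (cov + _COV_EPS * np.eye(history.shape[1]))


def sample_error_variance(ss_current: float, n: int, prior_shape: float,
                          prior_scale: float, rng) -> float:
    """Draw sigma^2 from its conjugate inverse-gamma full conditional
    IG(prior_shape + n/2, prior_scale + SS/2)."""
    if ss_current < 0 or n < 0:
        raise ValueError("ss and n must be non-negative")
    shape = prior_shape + 0.5 * n
    scale = prior_scale + 0.5 * ss_current
    return scale / rng.gamma(shape)


def _safe_cholesky(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        d = np.sqrt(np.maximum(np.diag(cov), _COV_EPS))
        return np.diag(d)


def run_dram(ss_fn, theta0, bounds, n_obs: int, config: SamplerConfig,
             param_names=None) -> ChainResult:
    """Run one DRAM chain over the parameters of ``ss_fn``.

    ``ss_fn`` maps a parameter array to a sum of squared (scaled)
    residuals; ``bounds = (lo, hi)`` arrays delimit the uniform prior
    box; ``n_obs`` is the number of scalar observations entering the
    Gaussian likelihood.  Burn-in is removed from the returned samples.
    Total objective evaluations are bounded by
    ``n_samples * max_dr_stages``.
    """
    theta0 = np.asarray(theta0, dtype=float)
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    k = len(theta0)
    if param_names is None:
        param_names = tuple(f"p{i}" for i in range(k))
    if np.any(theta0 < lo) or np.any(theta0 > hi):
        raise ValueError("theta0 must lie inside the prior bounds")

    rng = np.random.default_rng(config.seed)
    gamma = config.dr_downscale

    ss0 = float(ss_fn(theta0))
    if not math.isfinite(ss0):
        raise ValueError("objective is not finite at theta0")
    sigma2_hat = ss0 / max(n_obs - k, 1)
    prior_scale = (config.prior_scale if config.prior_scale is not None
                   else config.prior_shape * max(sigma2_hat, 1e-12))
    sigma2 = config.sigma2 if config.sigma2 is not None else max(sigma2_hat, 1e-12)

    # Initial proposal: diagonal at 5% of |theta0|, floored at 1e-4 of the
    # box width so parameters starting exactly at 0 can still move.
    scale = np.maximum(config.initial_scale * np.abs(theta0), 1e-4 * (hi - lo))
    chol = np.diag(scale)
    stages = _GaussStages(chol, gamma)

    all_samples = np.empty((config.n_samples, k))
    sigma2_all = np.empty(config.n_samples)
    stage_proposals = np.zeros(3, dtype=np.int64)
    stage_accepts = np.zeros(3, dtype=np.int64)
    n_evals = 1
    n_adapt = 0
    accepted_total = 0
    x, ss_x = theta0.copy(), ss0

    def kernel(theta, ss):
        return log_posterior_kernel(theta, ss, sigma2, (lo, hi))

    low_accept_warned = False
    window_accepts = 0
    for i in range(config.n_samples):
        lp_x = kernel(x, ss_x)
        points, lps, sss = [x], [lp_x], [ss_x]
        accepted = False
        for stage in range(1, config.max_dr_stages + 1):
            z = rng.standard_normal(k)
            y = x + (chol @ z) / gamma ** (stage - 1)
            if np.any(y < lo) or np.any(y > hi):
                ss_y = math.inf
            else:
                ss_y = float(ss_fn(y))
                n_evals += 1
            points.append(y)
            lps.append(kernel(y, ss_y))
            sss.append(ss_y)
            stage_proposals[stage - 1] += 1
            la = _log_alpha(points, lps, stages)
            if math.log(rng.uniform()) < la:
                stage_accepts[stage - 1] += 1
                x, ss_x = y, ss_y
                accepted = True
                break
        if accepted:
            accepted_total += 1
            window_accepts += 1
        if config.sample_sigma2:
            sigma2 = sample_error_variance(
                ss_x, n_obs, config.prior_shape, prior_scale, rng)
        all_samples[i] = x
        sigma2_all[i] = sigma2
        if (i + 1) % config.adapt_interval == 0:
            if i >= 1:
                cov = adapt_covariance(all_samples[: i + 1], k)
                chol = _safe_cholesky(cov)
                stages = _GaussStages(chol, gamma)
                n_adapt += 1
            if window_accepts < 0.001 * config.adapt_interval and not low_accept_warned:
                warnings.warn(
                    "DRAM acceptance below 0.1% over an adaptation window; "
                    "the chain may not be mixing", RuntimeWarning)
                low_accept_warned = True
            window_accepts = 0

    return ChainResult(
        samples=all_samples[config.burn_in:],
        sigma2_samples=sigma2_all[config.burn_in:],
        param_names=tuple(param_names),
        acceptance_rate=accepted_total / config.n_samples,
        stage_proposals=stage_proposals,
        stage_accepts=stage_accepts,
        n_evaluations=n_evals,
        adaptation_count=n_adapt,
        config=config,
        warning="low acceptance" if low_accept_warned else None,
    )
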