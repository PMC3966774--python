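"""Posterior summaries and information-theoretic model selection.

Models are compared by the residual sum of squares evaluated at the
componentwise posterior median ("RSS at median"), converted to the
small-sample-corrected Akaike criterion

    AICc = n ln(RSS/n) + 2k + 2k(k+1) / (n - k - 1),

with n the number of scalar observations (3 series x n_years) and k the
number of estimated parameters (the fitted ODE/initial-condition
parameters; equivalently the dynamical parameters plus the shared error
variance).  Relative support is expressed as Akaike weights
w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2) computed from unrounded
AICc values.
"""

from __future__ import annotations

import itertools
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dram import ChainResult
from .models import DEFAULT_BOUNDS, ModelSpec
from .objective import sum_of_squares, _theta_from_active

__all__ = [
    "posterior_summary",
    "rss_at_median",
    "aicc",
    "akaike_weights",
    "selection_table",
    "design_scan",
    "report",
]


def posterior_summary(chain: ChainResult) -> pd.DataFrame:
    """Mean, median and central 95% credibility interval per parameter
    (empirical quantiles, linear interpolation), from post-burn-in
    samples only."""
    s = chain.samples
    if s.size == 0:
        raise ValueError("chain is empty after burn-in")
    q = np.quantile(s, [0.025, 0.5, 0.975], axis=0)
    return pd.DataFrame(
        {
            "mean": s.mean(axis=0),
            "median": q[1],
            "ci_lower": q[0],
            "ci_upper": q[2],
        },
        index=list(chain.param_names),
    )


def rss_at_median(chain: ChainResult, model: ModelSpec, counts, factors=None,
                  dt: float = 0.02) -> float:
    """Scaled sum of squares at the vector of per-parameter posterior
    medians (not the best visited sample).  A median vector outside the
    prior box (possible for correlated posteriors hugging an edge) is
    evaluated anyway, with a warning."""
    med = chain.medians()
    lo, hi = model.bounds_arrays(DEFAULT_BOUNDS)
    if np.any(med < lo) or np.any(med > hi):
        warnings.warn("posterior median vector lies outside the prior box",
                      RuntimeWarning)
    theta = _theta_from_active(model, med)
    return sum_of_squares(theta, model, counts, factors, dt)


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample-corrected Akaike criterion from a residual sum of
    squares (Gaussian likelihood, variance profiled out)."""
    if rss <= 0:
        raise ValueError(f"rss must be positive, got {rss}")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 for the correction term (n={n}, k={k})")
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values):
    """(delta, weights): differences to the minimum AICc and normalised
    relative likelihoods exp(-delta/2)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size < 1:
        raise ValueError("need at least one model")
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return delta, w / w.sum()


def selection_table(rss_values, n: int, k_values, model_ids=None) -> pd.DataFrame:
    """Per-model RSS, k, AICc, Delta-AICc and Akaike weight."""
    rss_values = list(map(float, rss_values))
    k_values = list(map(int, k_values))
    if len(rss_values) != len(k_values):
        raise ValueError("rss_values and k_values must align")
    if model_ids is None:
        model_ids = list(range(1, len(rss_values) + 1))
    a = [aicc(r, n, k) for r, k in zip(rss_values, k_values)]
    delta, w = akaike_weights(a)
    return pd.DataFrame(
        {"model": model_ids, "rss": rss_values, "k": k_values, "n": n,
         "aicc": a, "delta_aicc": delta, "weight": w}
    ).set_index("model")


def design_scan(rss_values, aicc_values, n_range=(20, 200), k_range=(5, 20),
                tol: float = 0.01):
    """Brute-force recovery of the (n, k_1..k_m) design behind a printed
    selection table.

    Scans every sample size in ``n_range`` and, per model, every
    parameter count in ``k_range`` for configurations in which the AICc
    recomputed from the printed RSS matches the printed AICc to ``tol``.
    Returns a list of (n, (k_1, ..., k_m)) with one k per model; used to
    validate the parameter-count convention independently of any stated
    value.
    """
    matches = []
    for n in range(n_range[0], n_range[1] + 1):
        per_model = []
        for r, a in zip(rss_values, aicc_values):
            ks = [k for k in range(k_range[0], k_range[1] + 1)
                  if n > k + 1 and abs(aicc(r, n, k) - a) <= tol]
            if not ks:
                per_model = None
                break
            per_model.append(ks)
        if per_model is not None:
            for combo in itertools.product(*per_model):
                matches.append((n, combo))
    return matches


def _thin_indices(n: int, target: int) -> np.ndarray:
    if target < 1:
        raise ValueError("need at least one thinned sample")
    return np.unique(np.linspace(0, n - 1, min(target, n)).astype(int))


def report(results: dict, counts, table: pd.DataFrame, outdir,
           n_band_samples: int = 1000, dt: float = 0.02) -> dict:
    """Write the full report bundle for a set of fitted models.

    ``results`` maps model_id -> (ModelSpec, ChainResult).  Emits, per
    model: the trajectory at posterior-median parameters against the
    data with a 95% credibility band from evenly thinned posterior
    trajectories, trace plots, and marginal histograms; plus the
    selection table as JSON and CSV.  Returns the paths written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .models import integrate

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    t = counts.t_index.astype(float)
    horizon = float(counts.n_years - 1)
    labels = ("refuge elk", "valley elk", "valley wolves")

    for mid, (model, chain) in results.items():
        med = chain.medians()
        traj_med = integrate(model, _theta_from_active(model, med),
                             horizon=horizon, obs_times=t, dt=dt)
        idx = _thin_indices(len(chain.samples), n_band_samples)
        band = np.empty((len(idx), len(t), 3))
        for j, i in enumerate(idx):
            tr = integrate(model, _theta_from_active(model, chain.samples[i]),
                           horizon=horizon, obs_times=t, dt=dt)
            band[j] = tr.stacked()
        lo_band, hi_band = np.quantile(band, [0.025, 0.975], axis=0)

        fig, axes = plt.subplots(3, 1, figsize=(7, 9), sharex=True)
        obs = counts.stacked()
        pred = traj_med.stacked()
        for a, ax in enumerate(axes):
            ax.fill_between(t, lo_band[:, a], hi_band[:, a], color="0.8",
                            label="95% credibility band")
            ax.plot(t, pred[:, a], "-", color="k", label="median fit")
            ax.plot(t, obs[:, a], "o", ms=4, color="C0", label="counts")
            ax.set_ylabel(labels[a])
        axes[-1].set_xlabel("years since first winter")
        axes[0].legend(loc="best", fontsize=8)
        fig.suptitle(f"Model {mid} fit")
        p = outdir / f"model{mid}_fit.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths[f"model{mid}_fit"] = p

        k = chain.samples.shape[1]
        fig, axes = plt.subplots(k, 2, figsize=(9, 1.6 * k), squeeze=False)
        for a in range(k):
            axes[a, 0].plot(chain.samples[:, a], lw=0.3)
            axes[a, 0].set_ylabel(chain.param_names[a], fontsize=8)
            axes[a, 1].hist(chain.samples[:, a], bins=60, color="C0")
        axes[0, 0].set_title("trace")
        axes[0, 1].set_title("marginal posterior")
        fig.tight_layout()
        p = outdir / f"model{mid}_diagnostics.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths[f"model{mid}_diagnostics"] = p

    csv_path = outdir / "selection_table.csv"
    json_path = outdir / "selection_table.json"
    table.to_csv(csv_path)
    json_path.write_text(json.dumps(
        table.reset_index().to_dict(orient="records"), indent=2))
    paths["selection_csv"] = csv_path
    paths["selection_json"] = json_path
    return paths
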