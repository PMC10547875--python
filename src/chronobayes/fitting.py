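"""Maximum-likelihood fitting of the observer model.

Fits the two Weber fractions ``(w_m, w_r)`` to (t_s, t_r) pairs by maximizing
the likelihood of the response marginal p(t_r | t_s, w_m, w_r) with
Nelder-Mead restarts from a grid of initial values.  The search runs in
log-parameter space so positivity is structural.

The discrimination task has no reproduced intervals; instead each per-t_s1
psychometric fit (a cumulative Gaussian with mean mu and spread sigma) is
converted into a Gaussian *response* distribution with the same parameters,
pseudo-responses are drawn from it, and those (t_s1, pseudo_t_r) pairs are
fitted exactly like reproduction data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .observer import (
    N_NODES_TM,
    N_NODES_TS,
    ObserverParams,
    _gauss_legendre,
    _normal_pdf,
    _tm_window,
    bls_estimate,
)

__all__ = [
    "FitResult",
    "FitError",
    "DEFAULT_INIT_GRID",
    "negative_log_likelihood",
    "fit_observer",
    "fit_psychometric_contexts",
]

#: Default restart grid: all pairs from {0.05, 0.1, 0.2, 0.3} x {0.05, 0.1, 0.2, 0.3}.
DEFAULT_INIT_GRID = tuple(
    (wm, wr) for wm in (0.05, 0.1, 0.2, 0.3) for wr in (0.05, 0.1, 0.2, 0.3)
)

#: Log-densities below this are clamped to keep the NLL finite for outliers.
LOG_FLOOR = -745.0


class FitError(RuntimeError):
    """Raised when every restart of the simplex search fails to converge."""


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood observer fit."""

    params: ObserverParams
    nll: float
    n_trials: int
    converged: bool
    n_restarts_agreeing: int
    n_clamped: int = 0
    restarts: list = field(default_factory=list, repr=False)


def _prepare_trials(trials):
    arr = np.asarray(trials, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError("trials must be a nonempty sequence of (t_s, t_r) pairs")
    if np.any(arr[:, 0] <= 0):
        raise ValueError("all t_s must be positive")
    return arr


def negative_log_likelihood(
    trials,
    params: ObserverParams,
    n_nodes: int = N_NODES_TM,
    return_n_clamped: bool = False,
):
    """-sum(log p(t_r | t_s, params)) over trials, in nats.

    Trials are grouped by unique ``t_s`` so the BLS quadrature nodes are
    computed once per condition.  Log-densities below ``LOG_FLOOR`` are
    clamped (and counted) so a single wild outlier cannot make the objective
    infinite.
    """
    arr = _prepare_trials(trials)
    total = 0.0
    n_clamped = 0
    for t_s in np.unique(arr[:, 0]):
        t_r = arr[arr[:, 0] == t_s, 1]
        lo, hi = _tm_window(t_s, params.w_m)
        tm, wq = _gauss_legendre(lo, hi, n_nodes)
        te = bls_estimate(tm, params, n_nodes=N_NODES_TS)
        meas = _normal_pdf(tm, t_s, params.w_m * t_s)
        mot = _normal_pdf(t_r[:, None], te[None, :], params.w_r * te[None, :])
        dens = mot @ (wq * meas)
        with np.errstate(divide="ignore"):
            logd = np.log(dens)
        clamped = ~(logd > LOG_FLOOR)
        n_clamped += int(clamped.sum())
        logd = np.where(clamped, LOG_FLOOR, logd)
        total -= float(logd.sum())
    if return_n_clamped:
        return total, n_clamped
    return total


def fit_observer(
    trials,
    init_grid=DEFAULT_INIT_GRID,
    seed=None,
    prior_lo: float = 0.4,
    prior_hi: float = 1.9,
    xatol: float = 1e-6,
    fatol: float = 1e-6,
    agree_tol: float = 1e-3,
    max_fev: int = 500,
) -> FitResult:
    """Maximum-likelihood fit of ``(w_m, w_r)`` with Nelder-Mead restarts.

    Parameters
    ----------
    trials : sequence of (t_s, t_r)
        At least 20 trials spanning at least 2 distinct sample intervals.
    init_grid : sequence of (w_m, w_r)
        Restart initial values (optimized in log space from each).
    seed : int, optional
        Unused by the deterministic simplex search; accepted for interface
        symmetry with the stochastic stages.
    agree_tol : float
        Restarts whose optimum NLL is within this of the best one count as
        agreeing (a convergence diagnostic).

    Returns
    -------
    FitResult
        Best optimum over all restarts.
    """
    arr = _prepare_trials(trials)
    if arr.shape[0] < 20:
        raise ValueError(f"need at least 20 trials, got {arr.shape[0]}")
    if np.unique(arr[:, 0]).size < 2:
        raise ValueError("trials must span at least 2 distinct t_s values")

    def objective(log_params):
        w_m, w_r = np.exp(log_params)
        # keep the simplex away from degenerate corners
        if w_m < 1e-4 or w_r < 1e-4 or w_m > 5.0 or w_r > 5.0:
            return 1e12
        p = ObserverParams(w_m=w_m, w_r=w_r, prior_lo=prior_lo, prior_hi=prior_hi)
        return negative_log_likelihood(arr, p)

    results = []
    for wm0, wr0 in init_grid:
        res = optimize.minimize(
            objective,
            x0=np.log([wm0, wr0]),
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxfev": max_fev},
        )
        results.append(res)
    converged = [r for r in results if r.success and np.isfinite(r.fun)]
    if not converged:
        raise FitError(
            "no Nelder-Mead restart converged; statuses: "
            + "; ".join(f"{r.status}:{r.message}" for r in results)
        )
    best = min(converged, key=lambda r: r.fun)
    n_agree = sum(1 for r in converged if r.fun - best.fun <= agree_tol)
    w_m, w_r = np.exp(best.x)
    params = ObserverParams(w_m=float(w_m), w_r=float(w_r), prior_lo=prior_lo, prior_hi=prior_hi)
    nll, n_clamped = negative_log_likelihood(arr, params, return_n_clamped=True)
    return FitResult(
        params=params,
        nll=float(nll),
        n_trials=arr.shape[0],
        converged=True,
        n_restarts_agreeing=n_agree,
        n_clamped=n_clamped,
        restarts=[(tuple(np.exp(r.x)), float(r.fun), bool(r.success)) for r in results],
    )


def fit_psychometric_contexts(psych_fits, n_per_condition: int = 48, seed=None, rng=None):
    """Convert per-condition psychometric fits into pseudo-reproduction pairs.

    Each psychometric fit (cumulative Gaussian with mean ``mu`` and spread
    ``sigma`` for one reference interval ``t_s1``) is reinterpreted as a
    Gaussian response distribution Normal(mu, sigma); ``n_per_condition``
    draws are paired with that condition's ``t_s1``.  The output feeds
    :func:`fit_observer` unchanged.

    Parameters
    ----------
    psych_fits : sequence
        Non-excluded :class:`~chronobayes.stats.PsychometricFit` objects, one
        per reference interval.
    n_per_condition : int
        Pseudo-responses drawn per condition.
    seed, rng
        Seed or explicit generator for the draws.

    Returns
    -------
    ndarray of shape (len(psych_fits) * n_per_condition, 2)
        Columns (t_s1, pseudo_t_r), condition labels preserved in order.
    """
    fits = list(psych_fits)
    if not fits:
        raise ValueError("psych_fits must be nonempty")
    for f in fits:
        if getattr(f, "excluded", False):
            raise ValueError(f"excluded psychometric fit for t_s1={f.t_s1}")
        if not (np.isfinite(f.mu) and np.isfinite(f.sigma) and f.sigma > 0):
            raise ValueError(f"invalid psychometric fit for t_s1={f.t_s1}")
    if rng is None:
        rng = np.random.default_rng(seed)
    pairs = np.empty((len(fits) * n_per_condition, 2))
    for i, f in enumerate(fits):
        sl = slice(i * n_per_condition, (i + 1) * n_per_condition)
        pairs[sl, 0] = f.t_s1
        pairs[sl, 1] = rng.normal(f.mu, f.sigma, size=n_per_condition)
    return pairs
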