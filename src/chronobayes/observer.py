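"""Three-stage Bayesian observer model of interval timing.

The observer measures a sample interval ``t_s`` with scalar (Weber-like)
Gaussian noise, maps the noisy measurement ``t_m`` onto an estimate ``t_e``
with a Bayes least-squares (BLS) estimator over a uniform prior, and produces
a response ``t_r`` corrupted by scalar motor noise:

1. measurement:  ``t_m ~ Normal(t_s, w_m * t_s)``
2. estimation:   ``t_e = f(t_m) = E[t_s | t_m]`` under a uniform prior on
   ``[prior_lo, prior_hi]``
3. production:   ``t_r ~ Normal(t_e, w_r * t_e)``

The two Weber fractions ``w_m`` (measurement noise) and ``w_r`` (motor noise)
are the model's only free parameters.  The BLS stage is what produces the
central-tendency (Vierordt) bias: posterior means are pulled toward the
interior of the prior support, more strongly the noisier the measurement.

All intervals are in seconds.  Integrals are evaluated with fixed-node
Gauss-Legendre quadrature so that every quantity is deterministic and can be
checked against a brute-force trapezoid oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "ObserverParams",
    "PredictedResponseMoments",
    "BlsTable",
    "measurement_pdf",
    "bls_estimate",
    "motor_pdf",
    "response_pdf",
    "predicted_moments",
    "simulate_reproduction",
]

#: Sample intervals used in both tasks (seconds).
TS_VALUES = (0.4, 0.5, 0.7, 1.1, 1.9)

#: Default quadrature resolution for the t_s integral inside the BLS estimator.
N_NODES_TS = 513
#: Default quadrature resolution for the t_m integral inside the response marginal.
N_NODES_TM = 257
#: Lower floor for t_m integration windows (seconds); keeps t_m strictly positive.
TM_FLOOR = 1e-4
#: Half-width of the t_m integration window in units of the measurement sd.
TM_WINDOW_SDS = 8.0

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the three-stage observer.

    Parameters
    ----------
    w_m : float
        Measurement Weber fraction; sd of the measurement stage is
        ``w_m * t_s``.  Must be positive.
    w_r : float
        Motor Weber fraction; sd of the production stage is ``w_r * t_e``.
        Must be positive.
    prior_lo, prior_hi : float
        Support of the uniform prior over sample intervals (seconds).
    """

    w_m: float
    w_r: float
    prior_lo: float = 0.4
    prior_hi: float = 1.9

    def __post_init__(self) -> None:
        if not (self.w_m > 0 and np.isfinite(self.w_m)):
            raise ValueError(f"w_m must be positive and finite, got {self.w_m}")
        if not (self.w_r > 0 and np.isfinite(self.w_r)):
            raise ValueError(f"w_r must be positive and finite, got {self.w_r}")
        if not (0 < self.prior_lo < self.prior_hi):
            raise ValueError(
                f"prior support must satisfy 0 < lo < hi, got "
                f"[{self.prior_lo}, {self.prior_hi}]"
            )


@dataclass(frozen=True)
class PredictedResponseMoments:
    """Mean and sd of the response distribution p(t_r | t_s) (seconds)."""

    t_s: float
    mean_tr: float
    sd_tr: float


@lru_cache(maxsize=8)
def _leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


def _gauss_legendre(lo: float, hi: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = _leggauss(n)
    half = 0.5 * (hi - lo)
    return lo + half * (x + 1.0), half * w


def _normal_pdf(x: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    z = (x - mean) / sd
    return np.exp(-0.5 * z * z) / (_SQRT2PI * sd)


def measurement_pdf(t_m, t_s: float, w_m: float):
    """Density of the noisy measurement: Normal(t_s, w_m * t_s) at ``t_m``.

    ``t_m`` may be a scalar or array; ``t_s`` and ``w_m`` must be positive.
    """
    if not t_s > 0:
        raise ValueError(f"t_s must be positive, got {t_s}")
    if not w_m > 0:
        raise ValueError(f"w_m must be positive, got {w_m}")
    return _normal_pdf(np.asarray(t_m, dtype=float), t_s, w_m * t_s)


def motor_pdf(t_r, t_e: float, w_r: float):
    """Density of the produced interval: Normal(t_e, w_r * t_e) at ``t_r``.

    The motor Gaussian is supported on the whole real line (not truncated at
    zero), so the density is positive even at ``t_r <= 0``.
    """
    if not t_e > 0:
        raise ValueError(f"t_e must be positive, got {t_e}")
    if not w_r > 0:
        raise ValueError(f"w_r must be positive, got {w_r}")
    return _normal_pdf(np.asarray(t_r, dtype=float), t_e, w_r * t_e)


def bls_estimate(t_m, params: ObserverParams, n_nodes: int = N_NODES_TS):
    """Bayes least-squares estimate ``f(t_m)``: the posterior mean of t_s.

    Under a uniform prior on ``[prior_lo, prior_hi]`` the posterior mean is

        f(t_m) = int t_s p(t_m | t_s) dt_s / int p(t_m | t_s) dt_s

    with both integrals over the prior support.  The output always lies
    strictly inside the open support and is nondecreasing in ``t_m``.
    Measurements outside the support are legal inputs (they simply map to
    values near the closest edge).

    Parameters
    ----------
    t_m : float or array
        Noisy measurement(s), must be positive.
    params : ObserverParams
    n_nodes : int
        Gauss-Legendre node count for the t_s integral.
    """
    t_m_arr = np.atleast_1d(np.asarray(t_m, dtype=float))
    if np.any(t_m_arr <= 0):
        raise ValueError("t_m must be positive")
    lo, hi = params.prior_lo, params.prior_hi
    w_m = params.w_m
    x, w = _leggauss(n_nodes)
    # For small w_m the likelihood is a narrow spike that fixed nodes on the
    # full support would miss; integrate on a per-measurement window of
    # +/- 40 relative sds, clipped to the support (window-edge and saturation
    # tails are < 1e-300 there), with log-max subtraction against underflow.
    # Otherwise the spike is resolved and the scale-dependent tails matter:
    # integrate over the full support with shared nodes (the fast path).
    half = 40.0 * w_m
    if half < 0.6:
        w_lo = np.clip(t_m_arr * (1.0 - half), lo, hi)
        w_hi = np.clip(t_m_arr * (1.0 + half), lo, hi)
        mid = 0.5 * (w_hi + w_lo)[:, None]
        hw = 0.5 * (w_hi - w_lo)[:, None]
        ts = mid + hw * x[None, :]
        z = (t_m_arr[:, None] - ts) / (w_m * ts)
        logl = -0.5 * z * z - np.log(ts)  # 1/sd factor contributes -log t_s
        logl -= logl.max(axis=1, keepdims=True)
        lik = np.exp(logl) * (hw * w[None, :])
        num = (lik * ts).sum(axis=1)
        den = lik.sum(axis=1)
        degenerate = hw[:, 0] <= 0  # window collapsed onto a support edge
        out = np.where(degenerate, mid[:, 0], num / np.where(den > 0, den, 1.0))
    else:
        ts, wts = _gauss_legendre(lo, hi, n_nodes)
        lik = _normal_pdf(t_m_arr[:, None], ts[None, :], w_m * ts[None, :])
        num = lik @ (wts * ts)
        den = lik @ wts
        # pathological far-tail measurements: posterior collapses to an edge
        bad = den <= 0
        out = np.where(bad, np.where(t_m_arr < lo, lo, hi), num / np.where(bad, 1.0, den))
    return out if np.ndim(t_m) else float(out[0])


class BlsTable:
    """Precomputed BLS mapping on a dense t_m grid with linear interpolation.

    ``f(t_m)`` is smooth and monotone, so a monotone piecewise-linear
    interpolant over a dense grid reproduces it to well below 1e-5 s while
    making the response-marginal quadrature and large simulations cheap.
    The grid covers every t_m window used by :func:`response_pdf` for sample
    intervals inside the prior support.
    """

    def __init__(self, params: ObserverParams, n_grid: int = 4096, n_nodes: int = N_NODES_TS):
        self.params = params
        lo = max(TM_FLOOR, params.prior_lo * (1.0 - TM_WINDOW_SDS * params.w_m))
        hi = params.prior_hi * (1.0 + TM_WINDOW_SDS * params.w_m)
        self.grid = np.linspace(lo, hi, n_grid)
        self.values = bls_estimate(self.grid, params, n_nodes=n_nodes)

    def __call__(self, t_m):
        t_m = np.asarray(t_m, dtype=float)
        return np.interp(t_m, self.grid, self.values)


def _tm_window(t_s: float, w_m: float) -> tuple[float, float]:
    sd = w_m * t_s
    return max(TM_FLOOR, t_s - TM_WINDOW_SDS * sd), t_s + TM_WINDOW_SDS * sd


def response_pdf(
    t_r,
    t_s: float,
    params: ObserverParams,
    n_nodes: int = N_NODES_TM,
    bls=None,
):
    """Marginal response density p(t_r | t_s, w_m, w_r).

    Marginalizes the production density over the measurement distribution:

        p(t_r | t_s) = int p(t_r | f(t_m), w_r) p(t_m | t_s, w_m) dt_m

    evaluated by Gauss-Legendre quadrature on the window
    ``t_s +/- 6 w_m t_s`` (floored at a small positive value).

    Parameters
    ----------
    t_r : float or array
        Response value(s) at which to evaluate the density.
    t_s : float
        Sample interval (seconds).
    params : ObserverParams
    n_nodes : int
        Node count for the t_m quadrature.
    bls : callable, optional
        Precomputed BLS mapping (e.g. a :class:`BlsTable`); defaults to direct
        evaluation of :func:`bls_estimate`.
    """
    if not t_s > 0:
        raise ValueError(f"t_s must be positive, got {t_s}")
    t_r_arr = np.atleast_1d(np.asarray(t_r, dtype=float))
    lo, hi = _tm_window(t_s, params.w_m)
    tm, w = _gauss_legendre(lo, hi, n_nodes)
    te = bls(tm) if bls is not None else bls_estimate(tm, params)
    meas = _normal_pdf(tm, t_s, params.w_m * t_s)
    mot = _normal_pdf(t_r_arr[:, None], te[None, :], params.w_r * te[None, :])
    out = mot @ (w * meas)
    return out if np.ndim(t_r) else float(out[0])


def predicted_moments(
    t_s: float, params: ObserverParams, n_nodes: int = N_NODES_TM, bls=None
) -> PredictedResponseMoments:
    """Mean and sd of p(t_r | t_s) by quadrature over the measurement stage.

    Uses the law of total variance: conditional on ``t_m`` the response is
    Gaussian with mean ``t_e = f(t_m)`` and sd ``w_r t_e``, so

        E[t_r]   = E[t_e]
        Var[t_r] = w_r^2 E[t_e^2] + Var[t_e]

    with expectations over ``t_m ~ Normal(t_s, w_m t_s)``.
    """
    if not t_s > 0:
        raise ValueError(f"t_s must be positive, got {t_s}")
    lo, hi = _tm_window(t_s, params.w_m)
    tm, w = _gauss_legendre(lo, hi, n_nodes)
    te = bls(tm) if bls is not None else bls_estimate(tm, params)
    meas = _normal_pdf(tm, t_s, params.w_m * t_s)
    wm = w * meas
    z = wm.sum()  # ~1 up to truncation of the +/-6 sd window
    if not np.isfinite(z) or z <= 0:
        raise ArithmeticError(f"measurement quadrature degenerate at t_s={t_s}")
    e_te = float((wm @ te) / z)
    e_te2 = float((wm @ (te * te)) / z)
    var = params.w_r**2 * e_te2 + (e_te2 - e_te**2)
    return PredictedResponseMoments(t_s=t_s, mean_tr=e_te, sd_tr=float(np.sqrt(var)))


def simulate_reproduction(
    params: ObserverParams,
    t_s_list,
    seed=None,
    rng: np.random.Generator | None = None,
    bls=None,
) -> np.ndarray:
    """Draw one reproduction response per sample interval in ``t_s_list``.

    For each ``t_s``: draw ``t_m ~ Normal(t_s, w_m t_s)`` (redrawn if it falls
    at or below zero, which at realistic Weber fractions essentially never
    happens), compute ``t_e = f(t_m)``, draw ``t_r ~ Normal(t_e, w_r t_e)``.
    Deterministic given ``seed`` (or an explicit ``rng``).
    """
    t_s = np.asarray(t_s_list, dtype=float)
    if t_s.size == 0:
        raise ValueError("t_s_list must be nonempty")
    if np.any(t_s <= 0):
        raise ValueError("all sample intervals must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    t_m = rng.normal(t_s, params.w_m * t_s)
    # resample the (astronomically rare) nonpositive measurements
    bad = t_m <= TM_FLOOR
    while np.any(bad):
        t_m[bad] = rng.normal(t_s[bad], params.w_m * t_s[bad])
        bad = t_m <= TM_FLOOR
    f = bls if bls is not None else BlsTable(params)
    t_e = np.asarray(f(t_m), dtype=float)
    return rng.normal(t_e, params.w_r * t_e)
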