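import numpy as np
import pytest
from scipy.integrate import simpson

from chronobayes import ObserverParams


@pytest.fixture
def params():
    """A typical human-like observer: moderate measurement and motor noise."""
    return ObserverParams(w_m=0.2, w_r=0.15)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def trapezoid_bls(t_m: float, params: ObserverParams, n: int = 100_001) -> float:
    """Independent brute-force BLS oracle: dense trapezoid posterior mean."""
    ts = np.linspace(params.prior_lo, params.prior_hi, n)
    sd = params.w_m * ts
    lik = np.exp(-0.5 * ((t_m - ts) / sd) ** 2) / (np.sqrt(2 * np.pi) * sd)
    return np.trapezoid(ts * lik, ts) / np.trapezoid(lik, ts)


def brute_force_response_pdf(
    t_r: float, t_s: float, params: ObserverParams, n_m: int = 8_001, n_s: int = 5_001
) -> float:
    """Independent brute-force response marginal on a dense grid.

    Integrates the same marginal over the model's stated t_m window
    (t_s +/- 8 measurement sds, floored at 1e-4 s) — the window is part of
    the model's numerical definition; the oracle independently checks the
    quadrature over it.  All integrals use composite Simpson on dense
    uniform grids, whose O(h^4) error stays below 1e-8 even relative to
    deep-tail densities (trapezoid at this density would bottom out near
    1e-6 there).
    """
    sd_m = params.w_m * t_s
    tm = np.linspace(max(1e-4, t_s - 8 * sd_m), t_s + 8 * sd_m, n_m)
    ts = np.linspace(params.prior_lo, params.prior_hi, n_s)
    sd = params.w_m * ts
    # chunk over tm rows to keep the (n_m, n_s) likelihood out of memory
    te = np.empty(n_m)
    for start in range(0, n_m, 512):
        block = tm[start : start + 512, None]
        lik = np.exp(-0.5 * ((block - ts[None, :]) / sd) ** 2) / (np.sqrt(2 * np.pi) * sd)
        te[start : start + 512] = simpson(ts * lik, x=ts, axis=1) / simpson(
            lik, x=ts, axis=1
        )
    meas = np.exp(-0.5 * ((tm - t_s) / sd_m) ** 2) / (np.sqrt(2 * np.pi) * sd_m)
    sd_r = params.w_r * te
    mot = np.exp(-0.5 * ((t_r - te) / sd_r) ** 2) / (np.sqrt(2 * np.pi) * sd_r)
    return float(simpson(mot * meas, x=tm))
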