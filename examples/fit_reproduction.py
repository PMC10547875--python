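"""Maximum-likelihood recovery of observer parameters from reproduction data.

Simulates one subject's reproduction session (48 trials at each of the 5
sample intervals) from known Weber fractions, then fits the observer by
Nelder-Mead restarts and prints truth vs. estimate.  The two numbers to
compare are w_m (measurement noise, drives the central-tendency bias) and
w_r (motor noise, adds interval-proportional response scatter).
"""

import numpy as np

from chronobayes import ObserverParams, fit_observer, simulate_reproduction
from chronobayes.observer import TS_VALUES

true = ObserverParams(w_m=0.21, w_r=0.16)
t_s = np.repeat(np.asarray(TS_VALUES), 48)
t_r = simulate_reproduction(true, t_s, seed=7)
print(f"simulated {len(t_s)} trials from w_m={true.w_m}, w_r={true.w_r}")

res = fit_observer(np.column_stack([t_s, t_r]))
print(f"fitted: w_m={res.params.w_m:.3f}, w_r={res.params.w_r:.3f}")
print(f"negative log-likelihood {res.nll:.1f} nats over {res.n_trials} trials; "
      f"{res.n_restarts_agreeing}/16 restarts agree with the best optimum")
print("(estimates within ~0.01-0.02 of truth are typical at this trial count)")
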