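"""The three-stage Bayesian observer: shrinkage and central tendency.

Builds an observer with typical human Weber fractions, prints the BLS
mapping at the design intervals and the predicted response moments.  The
predicted means are pulled toward the interior of the prior support — short
intervals are overproduced and long ones underproduced (Vierordt's law) —
and the predicted sd grows with the interval (scalar variability).
"""

import numpy as np

from chronobayes import ObserverParams, bls_estimate, predicted_moments
from chronobayes.observer import TS_VALUES

params = ObserverParams(w_m=0.20, w_r=0.15)  # measurement / motor noise
print(f"observer: w_m={params.w_m}, w_r={params.w_r}, "
      f"prior on [{params.prior_lo}, {params.prior_hi}] s\n")

print(f"{'t_s':>5} {'f(t_s)':>8} {'E[t_r]':>8} {'sd[t_r]':>8} {'bias':>8}")
for t_s in TS_VALUES:
    m = predicted_moments(t_s, params)
    f = bls_estimate(t_s, params)
    print(f"{t_s:5.2f} {f:8.3f} {m.mean_tr:8.3f} {m.sd_tr:8.3f} {m.mean_tr - t_s:+8.3f}")

means = np.array([predicted_moments(t, params).mean_tr for t in TS_VALUES])
slope = np.polyfit(TS_VALUES, means, 1)[0]
print(f"\ncompression bias C = 1 - slope = {1 - slope:.3f}")
print("(positive C: responses regress toward the middle of the prior)")
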