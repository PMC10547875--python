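# chronobayes

Bayesian observer modelling of human interval timing across sensorimotor
domains (temporal reproduction vs. 2-AFC temporal discrimination) and
effectors (hand key press vs. saccadic eye movement).

Psychophysicists studying how people measure time face two robust empirical
signatures: the **central tendency** (Vierordt) bias — short intervals are
overestimated, long ones underestimated — and **scalar variability**
(Weber's law) — response variability grows with the interval.  Both emerge
naturally from a three-stage Bayesian observer:

1. **Measurement.** A sample interval *t*ₛ produces a noisy internal
   measurement *t*ₘ ~ 𝒩(*t*ₛ, *w*ₘ·*t*ₛ): the sd grows as a constant
   fraction *w*ₘ of the interval (the measurement Weber fraction).
2. **Estimation.** A Bayes least-squares (BLS) estimator maps *t*ₘ to the
   posterior mean over a uniform prior on [0.4, 1.9] s:
   *f*(*t*ₘ) = ∫ *t*ₛ *p*(*t*ₘ|*t*ₛ) d*t*ₛ ⁄ ∫ *p*(*t*ₘ|*t*ₛ) d*t*ₛ.
   Posterior means shrink toward the prior interior — this is where the
   central-tendency bias comes from.
3. **Production.** The response *t*ᵣ ~ 𝒩(*t*ₑ, *w*ᵣ·*t*ₑ) adds scalar motor
   noise *w*ᵣ.

The package fits (*w*ₘ, *w*ᵣ) per subject and context by maximum likelihood
of the marginal *p*(*t*ᵣ|*t*ₛ) (Nelder–Mead restarts in log space), computes
the behavioral statistics built on the model (compression bias
*C* = 1 − regression slope, indifference point IP, Weber regression of
variance on *t*ₛ², cumulative-Gaussian psychometric functions with PSE,
IQR outlier and subject exclusion cascades), runs the group-level inference
(2×2 repeated-measures ANOVA with partial η², Tukey HSD, Pearson
correlations between subject data and model predictions with Bonferroni
correction and default JZS Bayes factors), and simulates whole synthetic
cohorts of BLS observers for both tasks so the entire pipeline can be
exercised and validated end to end.

## Worked example

```python
import numpy as np
from chronobayes import ObserverParams, predicted_moments, fit_observer, simulate_reproduction
from chronobayes.observer import TS_VALUES

params = ObserverParams(w_m=0.20, w_r=0.15)
for t_s in TS_VALUES:
    m = predicted_moments(t_s, params)
    print(f"t_s={t_s:4.2f}  E[t_r]={m.mean_tr:.3f}  sd={m.sd_tr:.3f}")
```

prints

```
t_s=0.40  E[t_r]=0.517  sd=0.086
t_s=0.50  E[t_r]=0.582  sd=0.117
t_s=0.70  E[t_r]=0.772  sd=0.184
t_s=1.10  E[t_r]=1.162  sd=0.266
t_s=1.90  E[t_r]=1.631  sd=0.289
```

— the 0.4 s interval is overproduced by ~0.12 s and the 1.9 s interval
underproduced by ~0.27 s (central tendency), while the response sd grows
with the interval (scalar variability).  Fitting recovers the generating
parameters from a session-sized sample:

```python
t_s = np.repeat(TS_VALUES, 48)
t_r = simulate_reproduction(params, t_s, seed=7)
res = fit_observer(np.column_stack([t_s, t_r]))
print(res.params.w_m, res.params.w_r)   # ~0.20, ~0.15
```

The `examples/` directory holds one short script per capability
(`observer_model.py`, `fit_reproduction.py`, `discrimination_route.py`,
`bayes_factors.py`, `full_pipeline.py`).  A thin CLI wraps the pipeline:

```sh
chronobayes run --seed 1 --out results_dir        # simulate + full analysis
chronobayes simulate --seed 1 --out cohort_dir    # trial tables only
```

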