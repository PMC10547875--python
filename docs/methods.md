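# Methods

## The observer model

The observer is the standard three-stage Bayesian account of interval
timing: scalar Gaussian measurement noise, Bayes least-squares (BLS)
estimation under a uniform prior, scalar Gaussian motor noise.  The
marginal response density is

p(t_r | t_s, w_m, w_r) = ∫ 𝒩(t_r; f(t_m), w_r·f(t_m)) · 𝒩(t_m; t_s, w_m·t_s) dt_m,

with f the posterior mean under the uniform prior on [t_min, t_max].
Assumptions worth keeping in view:

- **Scalar noise at both ends.** Both noise sds are proportional to their
  means (Weber-like).  There is no additive noise floor; the Weber
  regression's intercept (`web_i`) in real data absorbs what this model
  omits.
- **Continuous uniform prior on [0.4, 1.9] s.**  The experiments present 5
  discrete intervals, but the estimator integrates continuously over the
  support, matching the model as usually written.  The support equals the
  presented range.
- **No truncation of the motor Gaussian at zero.**  At realistic Weber
  fractions the mass below zero is negligible; the density is left on the
  whole real line.
- **BLS mapping is not globally monotone.**  Because the measurement sd
  scales with t_s, the likelihood at t_m → 0 tends to ∝ 1/t_s and the
  posterior mean rises back toward (t_max − t_min)/ln(t_max/t_min) ≈ 0.96 s.
  f is monotone on the measurement range the tasks actually generate
  (t_m ≳ 0.3 s for w_m ≤ 0.3); the dip below that is a real property of the
  scalar-noise family, not a numerical artifact, and is irrelevant at the
  probability mass involved.

## Parameters

| parameter | meaning | units | default / typical |
|---|---|---|---|
| `w_m` | measurement Weber fraction | — | fitted; human range ≈ 0.15–0.26 |
| `w_r` | motor Weber fraction | — | fitted; human range ≈ 0.10–0.35 |
| `prior_lo`, `prior_hi` | prior support | s | 0.4, 1.9 (the presented range) |

## Numerics

All integrals are fixed-node Gauss–Legendre, chosen so every quantity is
deterministic and checkable against dense-trapezoid brute force:

- t_s integral inside the BLS estimator: 513 nodes on the prior support.
  For very small Weber fractions (w_m < 0.015) the likelihood is a spike
  that fixed nodes on the full support cannot resolve, so the integral
  switches to a per-measurement window of ±40 relative sds clipped to the
  support, with log-max subtraction against underflow; for larger w_m the
  scale-dependent tails matter and the full support is used;
- t_m integral inside the response marginal: 257 nodes on t_s ± 8·w_m·t_s,
  truncated below at 10⁻⁴ s.  The window is part of the model's numerical
  definition: the brute-force oracle integrates the same window with a
  dense trapezoid rule;
- agreement with the brute-force oracles is tested to 1e−6 relative error,
  and the response marginal normalizes to 1 within 1e−5.

`BlsTable` precomputes f on a 4096-point grid and interpolates linearly
(max error < 1e−5 s, tested) — used inside simulation loops where f is
evaluated millions of times.

Fitting maximizes the likelihood with Nelder–Mead from a 4×4 grid of starts
{0.05, 0.1, 0.2, 0.3}² (bracketing plausible human Weber fractions), in
log-parameter space so positivity is structural, with simplex tolerances
1e−6 on parameters and objective.  Log-densities below −745 are clamped
(and counted) so an outlier trial cannot make the objective infinite.
Restarts agreeing with the best optimum within 1e−3 nats are reported as a
convergence diagnostic.

## The discrimination route

2-AFC choices carry no reproduced interval, so the observer is fitted via
the psychometric transformation: each per-reference cumulative Gaussian
(mean = PSE, sd = discrimination spread) is reinterpreted as a Gaussian
*response* distribution with the same parameters; 48 pseudo-responses per
condition (one seeded draw, matching the per-condition trial count of the
task design) are paired with their reference interval and fitted exactly
like reproduction data.  This transform discards information, so the
recovery tolerance on w_m is ±0.05 versus ±0.02 through the reproduction
route.

## Behavioral statistics

- **Outlier filter:** Tukey fences at 1.5×IQR with type-7 (linearly
  interpolated) quartiles, applied per subject × effector × interval —
  responses scale with the interval, so pooled fences would systematically
  flag long-interval trials.
- **Central tendency:** OLS of the 5 condition means on the intervals;
  C = 1 − slope, IP = intercept/(1 − slope); slope = 1 yields an undefined
  IP, flagged rather than raised.
- **Weber regression:** OLS of response variance on t_s²; slope `web_s`
  (time-dependent), intercept `web_i` (time-independent); a negative slope
  is flagged, not rejected.
- **Psychometric fits:** unweighted least squares of Φ((t_s2 − μ)/σ), no
  lapse/guess parameters, multistart; goodness R is the Pearson correlation
  between observed and fitted proportions; R ≤ 0.50 excludes the condition.
- **Exclusion cascade:** conditions with R ≤ 0.50; subjects with more than
  two such conditions; subjects with an IP outside [0.4, 1.9] s (or
  undefined) in any context.  Idempotent, with every removal reported.
- **Bootstrap IP CI:** subjects (not trials) are resampled, B = 2000,
  percentile method; slope-1 resamples are redrawn and counted.

## Group inference

The 2×2 within-subject ANOVA tests each effect against its own
subject-by-effect interaction; partial η² = SS_eff/(SS_eff + SS_err).  With
two levels per factor sphericity is moot.  Tukey HSD compares the four cell
means using the pooled cells × subjects residual and the studentized range
with k = 4 — the error term for a within-subject design is a genuine
choice, made here for symmetry across the six comparisons.

The correlation table pairs each data context with each model context
within task (families of 4) plus the cross-task same-effector pairings
(families of 2), for bias (C) and variability (mean per-interval sd),
24 rows in all; Bonferroni correction is applied within each family.
Model-side bias and variability are computed by simulating responses from
the fitted parameters and pushing them through the identical
condition-mean pipeline as the data.

The Bayes factor is the default two-sided JZS correlation Bayes factor with
a uniform (stretched-beta, κ = 1) prior on ρ, computed by numerically
integrating the likelihood ratio of the exact sampling distribution of r
(hypergeometric form) over ρ ∈ (−1, 1).  Jeffreys's closed-form
approximation BF01 ≈ √((2n−3)/π)·(1−r²)^((n−4)/2) agrees within 10% for
n = 30, |r| ≤ 0.6 and serves as an independent cross-check, as does
pingouin's implementation in the test suite.

## Synthetic cohorts

The generator emulates the two task designs: reproduction blocks present
each of {0.4, 0.5, 0.7, 1.1, 1.9} s eight times in shuffled order
(40 trials/block, 6 blocks per effector context); discrimination blocks
present each (t_s1, ±{6, 12, 24, 48}%) pair once (40 trials/block,
12 blocks per effector context).  Cohort defaults: 30 subjects, per-context
(w_m, w_r) drawn uniformly from the mean ± sd ranges of the fitted group
values per context; a Gaussian copula couples each parameter's quantile
across a subject's contexts (default coupling 0.7 — good timers in one
context tend to be good in another, which is what gives the model-vs-data
correlation structure something to detect).  All randomness flows from one
seed through `SeedSequence` spawning, one child stream per subject.

**The discrimination choice rule is a modelling assumption.**  Choices are
generated by shrinking only the remembered first interval through the BLS
stage (t_e1 = f(t_m1)) and comparing the second raw measurement against it
(choice "long" iff t_m2 > t_e1).  Shrinking both intervals identically
would be order-equivalent to comparing raw measurements (f is monotone on
the relevant range) and would produce no PSE bias; the asymmetric rule
reproduces the PSE's regression toward the prior.  A consequence: the PSE
is unbiased not at the arithmetic prior midpoint but at the fixed point of
f (≈1.3 s for w_m = 0.2), which the tests assert.

What the generator does *not* emulate: sequential (trial-history) effects,
learning across blocks, lapses, feedback-driven recalibration, reaction
times, and any effector-specific response dynamics.  Passing tests
therefore validate the pipeline's correctness on data that satisfies the
model's assumptions, not the model's adequacy for real subjects.

## Problem sizes

Validation uses session-sized fits (240 trials per context, the 6-block
design), 20-subject recovery studies, 200-cohort bootstrap coverage runs at
B = 1000, and 1000 choices per psychometric point for the discrimination
route — sizes at which the checked tolerances (mean absolute recovery error
≤ 0.02; w_m within ±0.05 through the discrimination route; CI coverage
90–99%) are statistically meaningful.

## Known limitations

- The likelihood is evaluated by quadrature with fixed windows; Weber
  fractions far outside the human range (w_m > ~0.5) would need wider
  windows.
- The discrimination generative rule above is one of several defensible
  choices; fitted w_m through that route is interpretable only relative to
  it.
- Group inference assumes complete cases (all four contexts per subject)
  for the ANOVA/Tukey stage; incomplete subjects contribute to per-context
  summaries only.
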