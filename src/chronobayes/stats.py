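"""Per-subject behavioral statistics for the two timing tasks.

For each subject x task x effector context this module computes the
descriptive quantities that all group-level analyses consume:

* central tendency: OLS regression of mean response on sample interval;
  compression bias ``C = 1 - slope`` and indifference point
  ``IP = intercept / (1 - slope)`` (where the regression crosses unity);
* scalar variability: OLS regression of response variance on the squared
  interval; slope ``web_s`` (time-dependent, Weber) and intercept ``web_i``
  (time-independent);
* psychometric functions: per reference interval ``t_s1``, a cumulative
  Gaussian fitted to the proportion of "long" choices, yielding the point of
  subjective equality (PSE = mu) and spread sigma;
* trial/condition/subject exclusion rules and a bootstrap CI for the group
  indifference point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .observer import TS_VALUES

__all__ = [
    "PsychometricFit",
    "CentralTendencyFit",
    "WeberFit",
    "ContextSummary",
    "BootstrapCI",
    "ExclusionReport",
    "PsychometricFitError",
    "iqr_filter",
    "central_tendency_fit",
    "weber_fit",
    "psychometric_fit",
    "bootstrap_ip_ci",
    "apply_exclusions",
    "summarize_context",
]

#: Goodness-of-fit threshold: psychometric conditions with R <= this are excluded.
R_THRESHOLD = 0.50
#: Subjects with more than this many excluded psychometric conditions are dropped.
MAX_EXCLUDED_CONDITIONS = 2
#: Admissible indifference-point range (the presented interval range, seconds).
IP_RANGE = (0.4, 1.9)
#: Tukey-fence multiplier for the interquartile-range outlier filter.
IQR_MULTIPLIER = 1.5


class PsychometricFitError(RuntimeError):
    """Raised when the cumulative-Gaussian fit fails from every start."""


@dataclass
class PsychometricFit:
    """Cumulative-Gaussian fit for one reference interval.

    ``mu`` is the PSE, ``sigma`` the psychometric spread, ``R`` the Pearson
    correlation between observed and fitted proportions.  ``excluded`` is set
    iff ``R <= 0.50``.
    """

    t_s1: float
    mu: float
    sigma: float
    R: float
    excluded: bool


@dataclass
class CentralTendencyFit:
    slope: float
    intercept: float
    C: float
    IP: float
    ip_defined: bool = True
    ip_ci_lo: float = np.nan
    ip_ci_hi: float = np.nan


@dataclass
class WeberFit:
    web_s: float
    web_i: float
    negative_slope: bool = False


@dataclass
class ContextSummary:
    """Derived scalars for one subject x task x effector context."""

    subject_id: str
    task: str  # "reproduction" | "discrimination"
    effector: str  # "hand" | "eye"
    C: float
    IP: float
    web_s: float
    web_i: float
    w_m: float
    w_r: float
    interval_means: dict = field(default_factory=dict)
    interval_sds: dict = field(default_factory=dict)

    @property
    def mean_sd(self) -> float:
        """Mean of the per-interval response sds (the variability scalar)."""
        return float(np.mean(list(self.interval_sds.values())))


@dataclass
class BootstrapCI:
    lo: float
    hi: float
    n_redrawn: int = 0


def iqr_filter(values, multiplier: float = IQR_MULTIPLIER) -> np.ndarray:
    """Boolean outlier mask by the Tukey interquartile-range rule.

    Flags values outside ``[Q1 - k*IQR, Q3 + k*IQR]`` with linearly
    interpolated (type-7) quartiles.  A zero IQR flags nothing.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError(f"need at least 4 values for the IQR filter, got {v.size}")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        return np.zeros(v.size, dtype=bool)
    return (v < q1 - multiplier * iqr) | (v > q3 + multiplier * iqr)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple OLS slope and intercept."""
    xm, ym = x.mean(), y.mean()
    slope = float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())
    return slope, float(ym - slope * xm)


def central_tendency_fit(condition_means, require_full_design: bool = True) -> CentralTendencyFit:
    """Compression bias C and indifference point IP from condition means.

    Parameters
    ----------
    condition_means : sequence of (t_s, mean response)
        One pair per sample interval; by default all 5 design intervals must
        be present (relax with ``require_full_design=False`` for contexts
        where psychometric conditions were excluded).
    """
    arr = np.asarray(condition_means, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("condition_means must be (t_s, mean) pairs")
    if not np.all(np.isfinite(arr)):
        raise ValueError("condition means must be finite")
    design = np.asarray(TS_VALUES)
    if require_full_design:
        if arr.shape[0] != 5 or not np.allclose(np.sort(arr[:, 0]), design):
            raise ValueError(f"expected the 5 design intervals {TS_VALUES}")
    elif arr.shape[0] < 2:
        raise ValueError("need at least 2 condition means")
    slope, intercept = _ols(arr[:, 0], arr[:, 1])
    c = 1.0 - slope
    if abs(c) < 1e-9:
        return CentralTendencyFit(slope, intercept, C=c, IP=np.nan, ip_defined=False)
    return CentralTendencyFit(slope, intercept, C=c, IP=intercept / c, ip_defined=True)


def weber_fit(condition_stats) -> WeberFit:
    """Scalar-variability regression: response variance on squared interval.

    ``condition_stats`` holds (t_s**2, variance) pairs; the OLS slope is the
    time-dependent Weber parameter ``web_s`` and the intercept the
    time-independent ``web_i``.  A negative slope (possible under sampling
    noise) is flagged, not rejected.
    """
    arr = np.asarray(condition_stats, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("condition_stats must be >= 2 (t_s^2, variance) pairs")
    if not np.all(np.isfinite(arr)):
        raise ValueError("variances must be finite")
    slope, intercept = _ols(arr[:, 0], arr[:, 1])
    return WeberFit(web_s=slope, web_i=intercept, negative_slope=slope < 0)


def psychometric_fit(condition_props, t_s1: float | None = None) -> PsychometricFit:
    """Cumulative-Gaussian fit to choice proportions for one reference interval.

    Least-squares fit of ``Phi((t_s2 - mu) / sigma)`` to the proportion of
    "long" choices (no lapse/guess parameters, unweighted).  Goodness of fit
    ``R`` is the Pearson correlation between observed and fitted proportions;
    the fit is flagged ``excluded`` iff ``R <= 0.50`` (degenerate fits, e.g.
    flat data where sigma diverges, get ``R = 0``).
    """
    arr = np.asarray(condition_props, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("condition_props must be (t_s2, proportion) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if t_s1 is None:
        t_s1 = float(np.mean(x))
    span = float(x.max() - x.min())
    if span <= 0:
        raise ValueError("need at least two distinct t_s2 values")

    def model(params):
        mu, log_sigma = params
        return sps.norm.cdf((x - mu) / np.exp(log_sigma))

    starts = [
        (float(np.mean(x)), np.log(span / 4)),
        (float(np.mean(x)), np.log(span)),
        (float(x[np.argmin(np.abs(y - 0.5))]), np.log(span / 8)),
    ]
    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(lambda p: model(p) - y, x0=x0, method="lm")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise PsychometricFitError(f"cumulative-Gaussian fit failed for t_s1={t_s1}")
    mu, sigma = float(best.x[0]), float(np.exp(best.x[1]))
    fitted = model(best.x)
    if np.ptp(fitted) < 1e-12 or np.ptp(y) < 1e-12:
        r = 0.0  # flat observed or fitted curve: correlation undefined
    else:
        r = float(np.corrcoef(y, fitted)[0, 1])
        if np.isclose(r, 1.0):
            r = 1.0
    return PsychometricFit(t_s1=float(t_s1), mu=mu, sigma=sigma, R=r, excluded=r <= R_THRESHOLD)


def bootstrap_ip_ci(
    subject_condition_means,
    B: int = 2000,
    seed=None,
    rng=None,
    t_s_values=TS_VALUES,
) -> BootstrapCI:
    """Percentile bootstrap 95% CI for the group indifference point.

    Resamples *subjects* with replacement ``B`` times; each resample's group
    condition means are regressed on the sample intervals and the IP
    recomputed.  Resamples with an undefined IP (slope exactly 1) are redrawn
    and counted.
    """
    m = np.asarray(subject_condition_means, dtype=float)
    if m.ndim != 2 or m.shape[1] != len(t_s_values):
        raise ValueError(f"expected a (n_subjects, {len(t_s_values)}) table of condition means")
    n = m.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 subjects, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    ts = np.asarray(t_s_values, dtype=float)
    tsc = ts - ts.mean()
    denom = (tsc**2).sum()

    idx = rng.integers(0, n, size=(B, n))
    grp = m[idx].mean(axis=1)  # (B, n_conditions): group means per resample
    slope = (grp - grp.mean(axis=1, keepdims=True)) @ tsc / denom
    intercept = grp.mean(axis=1) - slope * ts.mean()
    n_redrawn = 0
    bad = np.abs(1.0 - slope) < 1e-9
    while np.any(bad):
        n_redrawn += int(bad.sum())
        ridx = rng.integers(0, n, size=(int(bad.sum()), n))
        rgrp = m[ridx].mean(axis=1)
        rslope = (rgrp - rgrp.mean(axis=1, keepdims=True)) @ tsc / denom
        rintercept = rgrp.mean(axis=1) - rslope * ts.mean()
        slope[bad], intercept[bad] = rslope, rintercept
        bad = np.abs(1.0 - slope) < 1e-9
    ip = intercept / (1.0 - slope)
    lo, hi = np.percentile(ip, [2.5, 97.5])
    return BootstrapCI(lo=float(lo), hi=float(hi), n_redrawn=n_redrawn)


@dataclass
class ExclusionReport:
    """Counts and identities produced by the exclusion cascade."""

    n_conditions_excluded: int = 0
    n_subjects_excluded_psychometric: int = 0
    n_subjects_excluded_ip: int = 0
    excluded_subjects: set = field(default_factory=set)
    details: list = field(default_factory=list)

    @property
    def n_subjects_excluded(self) -> int:
        return len(self.excluded_subjects)


def apply_exclusions(
    psych_table: pd.DataFrame | None,
    ip_table: pd.DataFrame,
) -> tuple[list, ExclusionReport]:
    """Run the subject-exclusion cascade and report every removal.

    Rules, in order:

    1. psychometric conditions with ``R <= 0.50`` are excluded (condition
       level; counted, not subject-removing by themselves);
    2. subjects with more than 2 excluded conditions (across effectors) are
       removed entirely;
    3. subjects whose indifference point falls outside [0.4, 1.9] s (or is
       undefined) in any task x effector context are removed.

    Parameters
    ----------
    psych_table : DataFrame or None
        Columns ``subject_id, effector, t_s1, R`` (one row per discrimination
        condition); ``None`` if there is no discrimination data.
    ip_table : DataFrame
        Columns ``subject_id, task, effector, IP`` (one row per context;
        NaN = undefined IP).

    Returns
    -------
    (kept_subject_ids, ExclusionReport)
        The cascade is idempotent: re-running it on the surviving subjects
        removes nothing further.
    """
    report = ExclusionReport()
    subjects = list(pd.unique(ip_table["subject_id"]))
    if psych_table is not None and len(psych_table):
        flagged = psych_table[psych_table["R"] <= R_THRESHOLD]
        report.n_conditions_excluded = len(flagged)
        counts = flagged.groupby("subject_id").size()
        for sid, k in counts.items():
            if k > MAX_EXCLUDED_CONDITIONS:
                report.excluded_subjects.add(sid)
                report.n_subjects_excluded_psychometric += 1
                report.details.append(
                    f"subject {sid}: {k} psychometric conditions with R <= {R_THRESHOLD}"
                )
    lo, hi = IP_RANGE
    for _, row in ip_table.iterrows():
        sid = row["subject_id"]
        ip = row["IP"]
        if not np.isfinite(ip) or ip < lo or ip > hi:
            if sid not in report.excluded_subjects:
                report.n_subjects_excluded_ip += 1
            report.excluded_subjects.add(sid)
            report.details.append(
                f"subject {sid}: IP = {ip} outside [{lo}, {hi}] "
                f"({row['task']}, {row['effector']})"
            )
    kept = [s for s in subjects if s not in report.excluded_subjects]
    return kept, report


def summarize_context(
    subject_id,
    task: str,
    effector: str,
    *,
    repro_trials: pd.DataFrame | None = None,
    psych_fits=None,
    fit=None,
) -> ContextSummary:
    """Assemble the derived scalars for one subject x task x effector.

    For reproduction contexts pass the (already outlier-filtered) trial table
    with columns ``t_s, t_r``; per-interval means and sds feed the central
    tendency and Weber regressions.  For discrimination contexts pass the
    per-``t_s1`` psychometric fits; PSE plays the role of the mean response
    and the psychometric sigma the role of the response sd.  ``fit`` is the
    observer :class:`~chronobayes.fitting.FitResult` for the context (or
    ``None``, leaving ``w_m``/``w_r`` as NaN).
    """
    if task == "reproduction":
        if repro_trials is None or not len(repro_trials):
            raise ValueError("reproduction context requires trials")
        g = repro_trials.groupby("t_s")["t_r"]
        means = g.mean()
        sds = g.std(ddof=1)
        if means.size < 5:
            raise ValueError(f"missing sample-interval conditions: have {list(means.index)}")
        mean_pairs = np.column_stack([means.index.to_numpy(), means.to_numpy()])
        var_pairs = np.column_stack([means.index.to_numpy() ** 2, sds.to_numpy() ** 2])
        interval_means = dict(zip(means.index, means))
        interval_sds = dict(zip(sds.index, sds))
        ct = central_tendency_fit(mean_pairs)
    elif task == "discrimination":
        fits = [f for f in (psych_fits or []) if not f.excluded]
        if len(fits) < 2:
            raise ValueError("discrimination context requires >= 2 usable psychometric fits")
        mean_pairs = np.array([[f.t_s1, f.mu] for f in fits])
        var_pairs = np.array([[f.t_s1**2, f.sigma**2] for f in fits])
        interval_means = {f.t_s1: f.mu for f in fits}
        interval_sds = {f.t_s1: f.sigma for f in fits}
        ct = central_tendency_fit(mean_pairs, require_full_design=len(fits) == 5)
    else:
        raise ValueError(f"unknown task {task!r}")
    wb = weber_fit(var_pairs)
    w_m = fit.params.w_m if fit is not None else np.nan
    w_r = fit.params.w_r if fit is not None else np.nan
    return ContextSummary(
        subject_id=subject_id,
        task=task,
        effector=effector,
        C=ct.C,
        IP=ct.IP if ct.ip_defined else np.nan,
        web_s=wb.web_s,
        web_i=wb.web_i,
        w_m=w_m,
        w_r=w_r,
        interval_means=interval_means,
        interval_sds=interval_sds,
    )
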