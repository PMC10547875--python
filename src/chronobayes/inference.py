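"""Group-level inference: repeated-measures ANOVA, Tukey HSD, and
model-vs-data Pearson correlations with Bonferroni correction and JZS Bayes
factors.

The 2x2 within-subject ANOVA (effector x task) uses the classical
sums-of-squares decomposition in which each effect is tested against its own
subject-by-effect interaction; effect size is partial eta squared.  Because
both factors have two levels, sphericity corrections are moot.

The Bayes factor is the default two-sided JZS correlation Bayes factor with a
uniform (stretched-beta, kappa = 1) prior on the population correlation rho,
computed by numerical integration of the likelihood ratio of the exact
sampling distribution of the sample correlation r:

    BF10 = int_{-1}^{1} (1/2) * p(r | rho, n) / p(r | 0, n) drho
    p(r | rho, n) prop-to (1 - rho^2)^((n-1)/2) (1 - rho r)^(-(n-3/2))
                  * 2F1(1/2, 1/2; (2n-1)/2; (rho r + 1)/2)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats as sps

__all__ = [
    "AnovaEffect",
    "CorrelationResult",
    "rm_anova_2x2",
    "tukey_hsd",
    "jzs_corr_bf10",
    "pearson_with_bf",
    "bonferroni",
    "build_correlation_matrix",
]

#: The four context labels: task (R/D) x effector (H/E).
CONTEXTS = ("R_H", "R_E", "D_H", "D_E")


@dataclass
class AnovaEffect:
    effect: str  # "effector" | "task" | "interaction"
    F: float
    p: float
    partial_eta_sq: float
    df: tuple = (1, 0)


@dataclass
class CorrelationResult:
    data_context: str
    model_context: str
    measure: str  # "bias" | "sd"
    r: float
    p_unc: float
    p_corr: float
    m: int
    bf10: float
    n: int


def _cell_array(cell_table) -> np.ndarray:
    """Coerce the input to an (n_subjects, 2, 2) array [subject, A, B]."""
    arr = np.asarray(cell_table, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 4:
        arr = arr.reshape(-1, 2, 2)
    if arr.ndim != 3 or arr.shape[1:] != (2, 2):
        raise ValueError("cell_table must have shape (n, 2, 2) or (n, 4)")
    if not np.all(np.isfinite(arr)):
        raise ValueError("incomplete design: every subject needs all 4 cells")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    return arr


def rm_anova_2x2(cell_table, factor_names=("effector", "task")) -> list[AnovaEffect]:
    """Two-way fully within-subject ANOVA on a 2x2 cell table.

    ``cell_table`` is (n_subjects, 2, 2), axis 1 the first factor, axis 2 the
    second, or an (n, 4) array with cells ordered (A1B1, A1B2, A2B1, A2B2).
    Each effect is tested against its own subject interaction:
    ``F_A = MS_A / MS_{A x subject}`` etc.; partial eta squared is
    ``SS_effect / (SS_effect + SS_error_effect)``.
    """
    y = _cell_array(cell_table)
    n = y.shape[0]
    grand = y.mean()
    subj = y.mean(axis=(1, 2))  # (n,)
    a = y.mean(axis=(0, 2))  # (2,)
    b = y.mean(axis=(0, 1))  # (2,)
    ab = y.mean(axis=0)  # (2, 2)
    as_ = y.mean(axis=2)  # (n, 2)
    bs = y.mean(axis=1)  # (n, 2)

    ss_a = 2 * n * ((a - grand) ** 2).sum()
    ss_b = 2 * n * ((b - grand) ** 2).sum()
    ss_ab = n * ((ab - a[:, None] - b[None, :] + grand) ** 2).sum()
    ss_as = 2 * ((as_ - a[None, :] - subj[:, None] + grand) ** 2).sum()
    ss_bs = 2 * ((bs - b[None, :] - subj[:, None] + grand) ** 2).sum()
    ss_subj = 4 * ((subj - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs
    ss_abs = max(ss_abs, 0.0)

    df_err = n - 1
    out = []
    for name, ss_eff, ss_err in (
        (factor_names[0], ss_a, ss_as),
        (factor_names[1], ss_b, ss_bs),
        ("interaction", ss_ab, ss_abs),
    ):
        ms_eff = ss_eff / 1.0
        ms_err = ss_err / df_err
        if ms_err > 0:
            f = ms_eff / ms_err
            p = float(sps.f.sf(f, 1, df_err))
        else:
            f, p = 0.0, 1.0  # no error variance: degenerate, report null
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        out.append(AnovaEffect(effect=name, F=float(f), p=p, partial_eta_sq=float(eta), df=(1, df_err)))
    return out


def tukey_hsd(cell_table, labels=CONTEXTS) -> pd.DataFrame:
    """Tukey HSD over the 4 within-subject cells.

    Pairwise comparisons of the 4 cell means using the pooled within-subject
    residual (cells x subjects interaction) as error term and the studentized
    range distribution with k = 4.
    """
    y = _cell_array(cell_table).reshape(-1, 4)
    n, k = y.shape
    grand = y.mean()
    subj = y.mean(axis=1)
    cell = y.mean(axis=0)
    resid = y - subj[:, None] - cell[None, :] + grand
    df_err = (n - 1) * (k - 1)
    ms_err = (resid**2).sum() / df_err
    se = np.sqrt(ms_err / n)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = cell[i] - cell[j]
            if ms_err > 0:
                q = abs(diff) / se
                p_adj = float(sps.studentized_range.sf(q, k, df_err))
                # unadjusted pairwise p (two-sided t on the same error term)
                p_unadj = float(2 * sps.t.sf(abs(diff) / (se * np.sqrt(2)), df_err))
            else:
                p_adj, p_unadj = 1.0, 1.0
            rows.append(
                {
                    "cell_1": labels[i],
                    "cell_2": labels[j],
                    "mean_diff": float(diff),
                    "p_adj": min(p_adj, 1.0),
                    "p_unadj": min(p_unadj, 1.0),
                }
            )
    return pd.DataFrame(rows)


def jzs_corr_bf10(r: float, n: int) -> float:
    """Default two-sided JZS Bayes factor for a Pearson correlation.

    Numerically integrates the likelihood ratio of the exact sampling
    distribution of r over a uniform prior on rho in (-1, 1) (the
    stretched-beta kappa = 1 default).  BF10 > 1 favors a nonzero population
    correlation.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"r must lie in [-1, 1], got {r}")
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if abs(r) == 1.0:
        return np.inf  # perfect correlation: evidence is unbounded
    c = (2 * n - 1) / 2.0
    den = special.hyp2f1(0.5, 0.5, c, 0.5)

    def lr(rho):
        return (
            (1 - rho**2) ** ((n - 1) / 2.0)
            * (1 - rho * r) ** (-(n - 1.5))
            * special.hyp2f1(0.5, 0.5, c, (rho * r + 1) / 2.0)
            / den
        )

    # the integrand peaks near rho = r; flag it as a difficult point
    val, _ = integrate.quad(lambda rho: 0.5 * lr(rho), -1.0, 1.0, limit=200, points=[r])
    return float(val)


def pearson_with_bf(x, y) -> tuple[float, float, float, int]:
    """Pearson r, two-sided p, JZS BF10 and n for paired observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 4:
        raise ValueError(f"need >= 4 paired finite values, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    res = sps.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    return r, p, jzs_corr_bf10(r, n), n


def bonferroni(p_unc: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, m * p)."""
    if not 0.0 <= p_unc <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p_unc}")
    if m < 1:
        raise ValueError(f"family size must be >= 1, got {m}")
    return min(1.0, m * p_unc)


#: (data_context, model_context, family size) for each comparison row.
#: Within-task blocks of four pairings are corrected with m = 4; the
#: cross-task same-effector rows with m = 2.
COMPARISON_PLAN = (
    ("R_H", "R_H", 4),
    ("R_H", "R_E", 4),
    ("R_E", "R_H", 4),
    ("R_E", "R_E", 4),
    ("D_H", "D_H", 4),
    ("D_H", "D_E", 4),
    ("D_E", "D_H", 4),
    ("D_E", "D_E", 4),
    ("R_H", "D_H", 2),
    ("D_H", "R_H", 2),
    ("R_E", "D_E", 2),
    ("D_E", "R_E", 2),
)


def build_correlation_matrix(
    data_table: pd.DataFrame, model_table: pd.DataFrame
) -> pd.DataFrame:
    """All model-vs-data correlations for bias and variability.

    Both tables carry one row per subject x context with columns
    ``subject_id, context, bias, sd`` (context in R_H/R_E/D_H/D_E; bias is
    the compression C, sd the mean per-interval response sd).  For each of
    the two measures, the 8 within-task pairings and the 4 cross-task
    same-effector pairings are computed -> 24 rows, with Bonferroni families
    of 4 (within-task) and 2 (cross-task).

    Subjects must match between the two tables for every context pairing.
    """
    rows = []
    for measure in ("bias", "sd"):
        for data_ctx, model_ctx, m in COMPARISON_PLAN:
            d = data_table[data_table["context"] == data_ctx].set_index("subject_id")[measure]
            mdl = model_table[model_table["context"] == model_ctx].set_index("subject_id")[measure]
            if not d.index.sort_values().equals(mdl.index.sort_values()):
                raise ValueError(
                    f"subject mismatch between data {data_ctx} and model {model_ctx}"
                )
            mdl = mdl.reindex(d.index)
            r, p, bf, n = pearson_with_bf(d.to_numpy(), mdl.to_numpy())
            rows.append(
                CorrelationResult(
                    data_context=data_ctx,
                    model_context=model_ctx,
                    measure=measure,
                    r=r,
                    p_unc=p,
                    p_corr=bonferroni(p, m),
                    m=m,
                    bf10=bf,
                    n=n,
                )
            )
    return pd.DataFrame([vars(c) for c in rows])
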