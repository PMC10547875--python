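"""Synthetic task designs and simulated cohorts of Bayesian observers.

Emulates the two experimental designs — temporal reproduction (measure a
flashed interval, reproduce it) and 2-AFC temporal discrimination (compare a
second interval to a first) — for both effectors (hand / eye), and simulates
whole cohorts of three-stage BLS observers with per-subject, per-context
Weber fractions.  Ground-truth parameters are returned alongside the trial
tables so recovery can be tested end to end.

Design constants: sample intervals {0.4, 0.5, 0.7, 1.1, 1.9} s; comparison
offsets +/- {6, 12, 24, 48}% of t_s1; 40 trials per block; reproduction runs
6 blocks and discrimination 12 blocks per effector context by default.

The generative rule for discrimination choices is a modelling assumption
(the observed choices do not pin it down): the *first* interval, held in
memory, is read out through the BLS stage (t_e1 = f(t_m1)) while the second
is compared as a raw measurement; the observer reports "long" iff
t_m2 > t_e1.  Shrinking only the remembered interval is what lets the PSE
regress toward the prior mean; shrinking both identically would be
order-equivalent to comparing raw measurements and would produce no PSE bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .observer import TM_FLOOR, TS_VALUES, BlsTable, ObserverParams, simulate_reproduction

__all__ = [
    "TaskDesign",
    "CohortSpec",
    "DELTAS",
    "DEFAULT_PARAM_RANGES",
    "make_design",
    "simulate_discrimination_choice",
    "simulate_subject",
    "simulate_cohort",
]

#: Relative comparison offsets for the discrimination task (fractions of t_s1).
DELTAS = (0.06, 0.12, 0.24, 0.48)

EFFECTORS = ("hand", "eye")
CONTEXTS = ("R_H", "R_E", "D_H", "D_E")

#: Per-context uniform ranges for the cohort parameter draws, spanning the
#: group mean +/- sd of the fitted Weber fractions per context
#: (reproduction/discrimination x hand/eye).
DEFAULT_PARAM_RANGES = {
    "R_H": {"w_m": (0.16, 0.26), "w_r": (0.11, 0.21)},
    "R_E": {"w_m": (0.16, 0.22), "w_r": (0.19, 0.29)},
    "D_H": {"w_m": (0.15, 0.21), "w_r": (0.13, 0.35)},
    "D_E": {"w_m": (0.16, 0.22), "w_r": (0.14, 0.34)},
}


@dataclass(frozen=True)
class TaskDesign:
    """Block structure of one task for one effector context."""

    task: str  # "reproduction" | "discrimination"
    n_blocks: int
    trials_per_block: int = 40
    t_s_values: tuple = TS_VALUES
    deltas: tuple = DELTAS

    def __post_init__(self):
        if self.task not in ("reproduction", "discrimination"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.trials_per_block != len(self.t_s_values) * 2 * len(self.deltas):
            raise ValueError("trials_per_block must equal 5 intervals x 8 conditions = 40")


def default_designs() -> dict:
    return {
        "reproduction": TaskDesign("reproduction", n_blocks=6),
        "discrimination": TaskDesign("discrimination", n_blocks=12),
    }


def make_design(task: str, n_blocks: int | None = None, seed=None, rng=None) -> pd.DataFrame:
    """Block-balanced pseudorandom trial schedule for one context.

    Reproduction blocks present each of the 5 sample intervals 8 times in
    shuffled order; discrimination blocks present each (t_s1, +/-delta) pair
    exactly once (5 x 8 = 40), shuffled.  Deterministic given ``seed``.
    """
    if n_blocks is None:
        n_blocks = default_designs()[task].n_blocks
    design = TaskDesign(task, n_blocks=n_blocks)
    if rng is None:
        rng = np.random.default_rng(seed)
    frames = []
    if task == "reproduction":
        base = np.repeat(np.asarray(design.t_s_values), 8)
        for b in range(n_blocks):
            order = rng.permutation(base.size)
            frames.append(pd.DataFrame({"block": b, "t_s": base[order]}))
    else:
        ts1 = np.repeat(np.asarray(design.t_s_values), 2 * len(design.deltas))
        signed = np.concatenate([np.asarray(design.deltas), -np.asarray(design.deltas)])
        delta = np.tile(signed, len(design.t_s_values))
        ts2 = ts1 * (1.0 + delta)
        for b in range(n_blocks):
            order = rng.permutation(ts1.size)
            frames.append(
                pd.DataFrame({"block": b, "t_s1": ts1[order], "t_s2": ts2[order]})
            )
    return pd.concat(frames, ignore_index=True)


def simulate_discrimination_choice(
    params: ObserverParams, t_s1, t_s2, seed=None, rng=None, bls=None
):
    """Simulate 2-AFC "long"/"short" choices for comparison trials.

    Draws ``t_m1 ~ N(t_s1, w_m t_s1)`` and ``t_m2 ~ N(t_s2, w_m t_s2)``,
    shrinks the remembered first interval through the BLS stage
    (``t_e1 = f(t_m1)``), and chooses "long" iff ``t_m2 > t_e1``.

    Returns a boolean array (True = "long"); scalar inputs give a scalar.
    """
    t1 = np.atleast_1d(np.asarray(t_s1, dtype=float))
    t2 = np.atleast_1d(np.asarray(t_s2, dtype=float))
    if t1.shape != t2.shape:
        raise ValueError("t_s1 and t_s2 must have the same shape")
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("intervals must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    if bls is None:
        bls = BlsTable(params)
    t_m1 = np.maximum(rng.normal(t1, params.w_m * t1), TM_FLOOR)
    t_m2 = rng.normal(t2, params.w_m * t2)
    t_e1 = np.asarray(bls(t_m1), dtype=float)
    long = t_m2 > t_e1
    return long if np.ndim(t_s1) else bool(long[0])


@dataclass(frozen=True)
class CohortSpec:
    """Population model for a simulated cohort.

    Per subject and context, ``w_m`` and ``w_r`` are drawn uniformly from
    ``param_ranges[context]``.  ``context_coupling`` correlates each
    parameter's quantile across a subject's four contexts through a Gaussian
    copula: 0 = independent contexts, 1 = identical quantile (and identical
    value when the ranges coincide).
    """

    n_subjects: int = 30
    context_coupling: float = 0.7
    seed: int = 0
    param_ranges: dict = field(default_factory=lambda: DEFAULT_PARAM_RANGES)
    designs: dict = field(default_factory=default_designs)

    def __post_init__(self):
        if not 0.0 <= self.context_coupling <= 1.0:
            raise ValueError("context_coupling must lie in [0, 1]")
        for ctx, ranges in self.param_ranges.items():
            for name, (lo, hi) in ranges.items():
                if not (0.0 < lo < hi < 1.0):
                    raise ValueError(f"{ctx}.{name} range must sit inside (0, 1)")


def _draw_params(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-subject, per-context (w_m, w_r) with copula coupling."""
    rho = spec.context_coupling
    rows = []
    for i in range(spec.n_subjects):
        z_shared = rng.standard_normal(2)  # one latent per parameter
        for ctx in CONTEXTS:
            z_ind = rng.standard_normal(2)
            z = rho * z_shared + np.sqrt(1.0 - rho**2) * z_ind
            u = sps.norm.cdf(z)
            lo_m, hi_m = spec.param_ranges[ctx]["w_m"]
            lo_r, hi_r = spec.param_ranges[ctx]["w_r"]
            rows.append(
                {
                    "subject_id": f"S{i:03d}",
                    "context": ctx,
                    "task": "reproduction" if ctx[0] == "R" else "discrimination",
                    "effector": "hand" if ctx[-1] == "H" else "eye",
                    "w_m": lo_m + u[0] * (hi_m - lo_m),
                    "w_r": lo_r + u[1] * (hi_r - lo_r),
                }
            )
    return pd.DataFrame(rows)


def simulate_subject(
    subject_id: str,
    params_by_context: dict,
    designs: dict | None = None,
    seed=None,
    rng=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one subject's full session: both tasks, both effectors.

    ``params_by_context`` maps each of R_H/R_E/D_H/D_E to its
    :class:`~chronobayes.observer.ObserverParams`.  Returns the reproduction
    and discrimination trial tables; deterministic given ``seed``.
    """
    if designs is None:
        designs = default_designs()
    if rng is None:
        rng = np.random.default_rng(seed)
    repro_frames, disc_frames = [], []
    for effector in EFFECTORS:
        ctx_r = f"R_{effector[0].upper()}"
        ctx_d = f"D_{effector[0].upper()}"
        p_r = params_by_context[ctx_r]
        p_d = params_by_context[ctx_d]
        sched = make_design("reproduction", designs["reproduction"].n_blocks, rng=rng)
        t_r = simulate_reproduction(p_r, sched["t_s"].to_numpy(), rng=rng)
        repro_frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "effector": effector,
                    "block": sched["block"],
                    "t_s": sched["t_s"],
                    "t_r": t_r,
                    "excluded": False,
                }
            )
        )
        sched = make_design("discrimination", designs["discrimination"].n_blocks, rng=rng)
        long = simulate_discrimination_choice(
            p_d, sched["t_s1"].to_numpy(), sched["t_s2"].to_numpy(), rng=rng
        )
        choice = np.where(long, "long", "short")
        correct = long == (sched["t_s2"].to_numpy() > sched["t_s1"].to_numpy())
        disc_frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "effector": effector,
                    "block": sched["block"],
                    "t_s1": sched["t_s1"],
                    "t_s2": sched["t_s2"],
                    "choice": choice,
                    "correct": correct,
                }
            )
        )
    return (
        pd.concat(repro_frames, ignore_index=True),
        pd.concat(disc_frames, ignore_index=True),
    )


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (reproduction, discrimination, truth).

    All randomness derives from ``spec.seed`` through a ``SeedSequence``:
    one child stream for the parameter draws, then one per subject, so any
    subject's data is reproducible in isolation.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_subjects + 1)
    truth = _draw_params(spec, np.random.default_rng(children[0]))
    repro_frames, disc_frames = [], []
    for i, sid in enumerate(truth["subject_id"].unique()):
        sub = truth[truth["subject_id"] == sid]
        params = {
            row["context"]: ObserverParams(w_m=row["w_m"], w_r=row["w_r"])
            for _, row in sub.iterrows()
        }
        r, d = simulate_subject(
            sid, params, spec.designs, rng=np.random.default_rng(children[i + 1])
        )
        repro_frames.append(r)
        disc_frames.append(d)
    return (
        pd.concat(repro_frames, ignore_index=True),
        pd.concat(disc_frames, ignore_index=True),
        truth,
    )
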