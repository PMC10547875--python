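"""CSV schemas and validation for trial tables.

CSV is the interchange format: UTF-8, header row required, intervals in
seconds as decimal floats.  Two schemas exist, one per task; see
``REPRODUCTION_COLUMNS`` and ``DISCRIMINATION_COLUMNS``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .observer import TS_VALUES
from .simulate import DELTAS

__all__ = [
    "SchemaError",
    "REPRODUCTION_COLUMNS",
    "DISCRIMINATION_COLUMNS",
    "validate_trial_table",
    "read_trial_table",
]

REPRODUCTION_COLUMNS = ("subject_id", "effector", "block", "t_s", "t_r")
DISCRIMINATION_COLUMNS = ("subject_id", "effector", "block", "t_s1", "t_s2", "choice")

_T_R_RANGE = (0.0, 10.0)
_RATIOS = tuple(1.0 + d for d in DELTAS) + tuple(1.0 - d for d in DELTAS)


class SchemaError(ValueError):
    """A trial table violates its schema; carries per-row messages."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        preview = "; ".join(violations[:10])
        more = f" (+{len(violations) - 10} more)" if len(violations) > 10 else ""
        super().__init__(f"{len(violations)} schema violation(s): {preview}{more}")


def _in_set(values: np.ndarray, allowed, tol: float = 1e-9) -> np.ndarray:
    allowed = np.asarray(allowed, dtype=float)
    return np.any(np.abs(values[:, None] - allowed[None, :]) <= tol, axis=1)


def validate_trial_table(table: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Validate a trial table against the reproduction/discrimination schema.

    Checks column presence, effector labels, interval design membership, the
    response range, the t_s2/t_s1 ratio invariant and choice labels.  Raises
    :class:`SchemaError` naming each offending row; returns the table
    (with a recomputed ``correct`` column for discrimination) if clean.
    """
    if kind not in ("reproduction", "discrimination"):
        raise ValueError(f"unknown table kind {kind!r}")
    required = REPRODUCTION_COLUMNS if kind == "reproduction" else DISCRIMINATION_COLUMNS
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError([f"missing column(s): {', '.join(missing)}"])
    v: list[str] = []
    bad_eff = ~table["effector"].isin(["hand", "eye"])
    for i in table.index[bad_eff]:
        v.append(f"row {i}: effector {table.at[i, 'effector']!r} not in {{hand, eye}}")
    if kind == "reproduction":
        ts = table["t_s"].to_numpy(dtype=float)
        ok = _in_set(ts, TS_VALUES)
        for i in np.flatnonzero(~ok):
            v.append(f"row {table.index[i]}: t_s = {ts[i]} not a design value {TS_VALUES}")
        tr = table["t_r"].to_numpy(dtype=float)
        bad = ~((tr > _T_R_RANGE[0]) & (tr < _T_R_RANGE[1]))
        for i in np.flatnonzero(bad):
            v.append(f"row {table.index[i]}: t_r = {tr[i]} outside {_T_R_RANGE}")
    else:
        ts1 = table["t_s1"].to_numpy(dtype=float)
        ts2 = table["t_s2"].to_numpy(dtype=float)
        ok1 = _in_set(ts1, TS_VALUES)
        for i in np.flatnonzero(~ok1):
            v.append(f"row {table.index[i]}: t_s1 = {ts1[i]} not a design value {TS_VALUES}")
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(ts1 > 0, ts2 / ts1, np.nan)
        okr = _in_set(ratio, _RATIOS)
        for i in np.flatnonzero(~okr & ok1):
            v.append(
                f"row {table.index[i]}: t_s2/t_s1 = {ratio[i]:.6f} not in +/-{DELTAS}"
            )
        bad_choice = ~table["choice"].isin(["long", "short"])
        for i in table.index[bad_choice]:
            v.append(f"row {i}: choice {table.at[i, 'choice']!r} not in {{long, short}}")
    if v:
        raise SchemaError(v)
    out = table.copy()
    if kind == "discrimination":
        out["correct"] = (out["choice"] == "long") == (
            out["t_s2"].to_numpy() > out["t_s1"].to_numpy()
        )
    elif "excluded" not in out.columns:
        out["excluded"] = False
    return out


def read_trial_table(path, kind: str) -> pd.DataFrame:
    """Read and validate a trial CSV."""
    return validate_trial_table(pd.read_csv(path), kind)
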