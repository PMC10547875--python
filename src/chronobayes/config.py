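"""Pipeline configuration.

Every threshold defaults to the analysis constants of the study design: IQR
fence multiplier 1.5, psychometric goodness threshold R <= 0.50,
indifference-point range [0.4, 1.9] s, bootstrap B = 2000, 48 pseudo-
responses per discrimination condition.  A single integer seed drives every
random stage.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .fitting import DEFAULT_INIT_GRID
from .simulate import DEFAULT_PARAM_RANGES

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    seed: int = 0
    # cohort
    n_subjects: int = 30
    context_coupling: float = 0.7
    param_ranges: dict = field(default_factory=lambda: {
        ctx: {k: list(v) for k, v in ranges.items()}
        for ctx, ranges in DEFAULT_PARAM_RANGES.items()
    })
    # design
    n_blocks_reproduction: int = 6
    n_blocks_discrimination: int = 12
    # fitting
    init_grid: list = field(default_factory=lambda: [list(p) for p in DEFAULT_INIT_GRID])
    xatol: float = 1e-6
    fatol: float = 1e-6
    max_fev: int = 500
    n_per_condition: int = 48
    # model-prediction simulation
    n_sim_per_condition: int = 48
    # exclusion thresholds
    iqr_multiplier: float = 1.5
    r_threshold: float = 0.50
    ip_range: tuple = (0.4, 1.9)
    # bootstrap
    bootstrap_B: int = 2000
    # output
    outdir: str = "chronobayes_out"
    verbose: bool = False

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["ip_range"] = list(d["ip_range"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        out = cls(**d)
        out.ip_range = tuple(out.ip_range)
        return out
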