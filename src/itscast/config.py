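"""Run configuration: YAML-backed settings for the command-line pipeline.

One global seed fans out to per-stage seeds by fixed offsets so each stage
(simulation, tuning, evaluation, bootstrap) is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["RunConfig", "load_config", "STAGE_SEED_OFFSETS"]

STAGE_SEED_OFFSETS = {"simulate": 0, "tune": 1, "evaluate": 2, "counterfactual": 3}


@dataclass
class RunConfig:
    # input
    input_path: Optional[str] = None
    column_map: dict = field(default_factory=dict)
    date_column: str = "date"
    outcome_column: str = "y"
    # timeline
    train_end: Optional[str] = None
    test_end: Optional[str] = None
    event_start: Optional[str] = None
    event_end: Optional[str] = None
    post_extra_end: Optional[str] = None
    # threshold rule alternative to an explicit event window
    event_column: str = "smoke_pm25"
    event_threshold: float = 35.0
    event_min_run: int = 1
    # search
    n_configs: dict = field(
        default_factory=lambda: {"arima": 100, "nnar": 75, "hybrid": 100}
    )
    cv_initial_years: float = 2.9
    cv_validation_months: int = 12
    cv_folds: int = 5
    # bootstrap
    mbb_B: int = 1000
    mbb_L: object = 14  # int or "auto"
    # simulation
    sim_scale: str = "small"
    sim_rr: float = 1.15
    seed: int = 0
    output_dir: str = "itscast_out"

    def __post_init__(self):
        for fam, n in self.n_configs.items():
            if n < 1:
                raise ValueError(f"n_configs[{fam!r}] must be >= 1")
        if self.mbb_B < 1:
            raise ValueError("mbb_B must be >= 1")

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + STAGE_SEED_OFFSETS[stage]

    @property
    def outdir(self) -> Path:
        p = Path(self.output_dir)
        p.mkdir(parents=True, exist_ok=True)
        return p


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)
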