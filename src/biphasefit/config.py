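"""Analysis configuration: thresholds, optimizer settings, reproducibility.

All tunable knobs live in one frozen dataclass so every report can embed the
exact configuration that produced it. YAML loading rejects unknown keys.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = ["AnalysisConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    # model preference
    rmse_ratio_threshold: float = 2.0  # mono/biphasic RMSE ratio to prefer biphasic
    # fitting
    use_replicate_means: bool = False  # fit on all replicate points by default
    f1_starts: tuple = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
    kd_starts_per_axis: int = 4
    # classification thresholds (LV/NI are package choices, MP's 0.85 is canonical)
    lv_threshold: float = 0.35  # mean viability below this (and flat) -> LV
    lv_range: float = 0.2
    ni_threshold: float = 0.20  # max inhibition below this -> NI
    f1_mp_threshold: float = 0.85  # F1 at/above this -> monophasic category
    # QC
    qc_rmse_threshold: float = 0.15
    qc_jump_threshold: float = 0.25
    # synergy
    dri_levels: tuple = (0.4, 0.5, 0.6, 0.7)
    icx_method: str = "interpolated"  # or "from_fit"
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f1_mp_threshold <= 1:
            raise ValueError("f1_mp_threshold must be in (0, 1]")
        for name in ("lv_threshold", "ni_threshold", "qc_rmse_threshold",
                     "qc_jump_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rmse_ratio_threshold < 1:
            raise ValueError("rmse_ratio_threshold must be >= 1")
        if self.icx_method not in ("interpolated", "from_fit"):
            raise ValueError(f"unknown icx_method {self.icx_method!r}")
        object.__setattr__(self, "f1_starts", tuple(self.f1_starts))
        object.__setattr__(self, "dri_levels", tuple(self.dri_levels))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)
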