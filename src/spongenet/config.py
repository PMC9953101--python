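"""Flat key-value pipeline configuration with validated thresholds."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Defaults are the published thresholds; ranges are enforced."""

    scc: float = -0.7
    pcc: float = 0.9
    alpha: float = 0.05
    lfc: float = 1.0
    fdr: float = 0.05
    min_len: int = 200
    pseudocount: float = 1.0
    universe_policy: str = "de_targets"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not -1.0 <= self.scc < 0.0:
            raise ValueError("scc must lie in [-1, 0)")
        if not 0.0 < self.pcc <= 1.0:
            raise ValueError("pcc must lie in (0, 1]")
        for name in ("alpha", "fdr"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.lfc < 0:
            raise ValueError("lfc must be >= 0")
        if self.min_len < 0:
            raise ValueError("min_len must be >= 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.universe_policy not in ("de_targets", "table", "matrix"):
            raise ValueError(f"unknown universe_policy {self.universe_policy!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
        return cls(**data)
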