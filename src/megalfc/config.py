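"""Analysis configuration with YAML round-trip.

All defaults are the pipeline's canonical thresholds: significance
p < 1e-7 with LFC > 0.49 or < -0.74, auto model selection, per-sample
median-scale normalization, linear-scale detection at max > 50, and a
20,000-gene background for overlap significance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from . import meta
from .genesets import DEFAULT_UNIVERSE
from .studies import LOG_DETECT_THRESHOLD


@dataclass
class AnalysisConfig:
    alpha: float = meta.ALPHA
    lfc_up: float = meta.LFC_UP
    lfc_down: float = meta.LFC_DOWN
    model: str = "auto"
    partial: bool = True
    normalization: str = "median-scale"
    log_detect_threshold: float = LOG_DETECT_THRESHOLD
    universe: int = DEFAULT_UNIVERSE

    def __post_init__(self) -> None:
        if not self.lfc_up > 0 > self.lfc_down:
            raise ValueError("need lfc_up > 0 > lfc_down")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.model not in ("auto", "fixed", "random"):
            raise ValueError(f"unknown model {self.model!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
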