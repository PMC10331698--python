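"""Pipeline configuration.

All thresholds are on the Log10Ratio scale (log10 fold-change versus the
plate vehicle mean) unless noted.  Defaults reproduce the screening study's
processing choices: a −0.3 overt-cytotoxicity threshold, a 20% effect size
(|Log10Ratio| > 0.1) for envelope-gated signature rules, the
max(3·bmad, log10 1.2) response cutoff, the 95% historical-control envelope,
and the r > 0.6 / top-10 similarity search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # thresholds (Log10Ratio scale unless noted)
    cytotox_log10ratio: float = -0.3
    effect_size: float = 0.1
    coff_floor_fold: float = 1.2          # fold-change floor for the hit cutoff
    envelope_coverage: float = 0.95
    similarity_r_min: float = 0.6
    similarity_top_k: int = 10
    max_cytotox_endpoints_for_profiling: int = 2
    nonspecific_cytotox_min: int = 2

    # strictness / method switches
    overt_strict: bool = True             # overt flagging uses "<" (vs "<=")
    signature_cytotox_strict: bool = False  # signature rules use "<=" for -0.3
    envelope_method: str = "quantile"     # or "normal" (normal-theory interval)
    mad_scale: float = 1.4826             # MAD consistency constant (1.0 alt.)

    # SOM
    som_full_grid: tuple[int, int] = (7, 7)
    som_filtered_grid: tuple[int, int] = (6, 6)
    som_epochs: int = 100

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.envelope_coverage < 1.0:
            raise ValueError("envelope_coverage must be in (0, 1)")
        if self.coff_floor_fold <= 1.0:
            raise ValueError("coff_floor_fold must exceed 1")
        if self.envelope_method not in ("quantile", "normal"):
            raise ValueError(f"unknown envelope_method {self.envelope_method!r}")
        for name in ("cytotox_log10ratio", "effect_size", "similarity_r_min",
                     "mad_scale"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def coff_floor(self) -> float:
        """The fold-change floor expressed as a Log10Ratio."""
        return math.log10(self.coff_floor_fold)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["som_full_grid"] = list(self.som_full_grid)
        d["som_filtered_grid"] = list(self.som_filtered_grid)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("som_full_grid", "som_filtered_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
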