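"""Pipeline configuration: the screening thresholds and their defaults.

Defaults mirror the published screen: cis-eQTL significance at p = 1e-5
within a 500 kb window of the gene body, LD proxies at r^2 >= 0.8 within
500 kb, and a 7-mer seed match as the positive-prediction cutoff.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    eqtl_p_cutoff: float = 1e-5
    cis_window_bp: int = 500_000
    ld_r2_cutoff: float = 0.8
    ld_window_bp: int = 500_000
    min_match_len: int = 7
    flank_bp: int = 2_000
    coexpression_threshold: float = 0.0
    change_includes_position: bool = True  # else "change" requires a type change
    require_coexpression: bool = False  # enrichment statistic variant
    maf_tolerance: float = 0.05
    permutations: int = 999
    rescan_window: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.eqtl_p_cutoff < 1.0:
            raise ValueError("eqtl_p_cutoff must be in (0, 1)")
        if not 0.0 < self.ld_r2_cutoff <= 1.0:
            raise ValueError("ld_r2_cutoff must be in (0, 1]")
        for name in ("cis_window_bp", "ld_window_bp", "min_match_len",
                     "flank_bp", "maf_tolerance", "permutations", "rescan_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config; keyword overrides (CLI flags) win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
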