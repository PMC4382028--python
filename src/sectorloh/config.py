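"""Pipeline configuration: a flat, validated key-value file (YAML).

Every field has a default; unknown keys are rejected rather than ignored so
that a typo cannot silently fall back to a default.  Stochastic commands
require an explicit seed — a run without one fails instead of silently
randomizing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # zygosity calling
    het_lo: float = 0.7
    het_hi: float = 1.3
    hom_present_min: float = 1.4
    hom_absent_max: float = 0.6
    # segmentation smoothing
    min_run: int = 2
    smooth_window: int = 3
    # simulation
    n_snps: int = 2300
    chrom_length: int = 1_100_000
    p_no_gc: float = 0.13
    p_g1: float = 0.75
    median_tract_bp: float = 10_600.0
    tract_sigma: float = 0.9
    noise_sd: float = 0.12
    patchy_switch_rate: float = 0.0
    # enrichment
    midpoint_classes: tuple[str, ...] = ("Ty",)
    merge_windows: bool = False
    # run control
    seed: int | None = None
    output_dir: str = "results"

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError(
                "stochastic commands require an explicit seed (set `seed:` in "
                "the config or pass --seed)"
            )
        return self.seed

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {unknown}")
    if "midpoint_classes" in raw and raw["midpoint_classes"] is not None:
        raw["midpoint_classes"] = tuple(raw["midpoint_classes"])
    return PipelineConfig(**raw)
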