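"""Run configuration shared by the pipeline stages.

Defaults are the published array-design and classification parameters:
12-mer tiles stepped every 2 residues, 5 wild-type replicates, background
from the lower 70-percentile, binder threshold at mean + 10 SD.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # tiling
    k: int = 12
    step: int = 2
    force_terminal: bool = True
    # replication / variant handling
    replicates_wt: int = 5
    replicates_variant: int = 1
    drop_wt_collisions: bool = False
    # classification
    percentile: float = 70.0
    k_sd: float = 10.0
    min_replicates: int = 3
    percentile_method: str = "nearest_rank"
    # alanine effects
    epsilon: float = 1.0
    orientation: str = "variant_over_wt"
    # synthetic data
    background_mean: float = 50.0
    background_sd: float = 8.0
    replicate_sd: float = 8.0
    amplitude: float = 160.0
    knockdown: float = 0.25
    n_toxins: int = 30
    n_epitopes: int = 10
    # randomness
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        """Stable short digest identifying this parameter set."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
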