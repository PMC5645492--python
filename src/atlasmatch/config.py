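"""Run configuration shared by the library, CLI and acceptance tooling."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Tunable parameters of the matching and DE pipeline.

    Defaults mirror the published analysis where it states them: probes and
    regions must be seen in at least two samples, differential genes require
    a Benjamini-Hochberg adjusted p below 0.01 and an absolute log2
    fold-change of at least 1.5.
    """

    min_samples: int = 2
    detection_threshold: float = 0.0
    collapse: str = "mean"          # probe -> gene collapsing rule
    min_genes: int = 100            # minimum shared gene index for scoring
    background_cap: int = 10        # background size cap, multiples of G
    exact_limit: int = 20           # exact Wilcoxon up to this pooled n
    signed_rank_diff: bool = False  # signed instead of absolute differences
    neglog10_cap: float = 320.0
    alpha: float = 0.01
    lfc_threshold: float = 1.5      # log2 units
    var_floor: float = 1e-8
    pseudocount: float = 1.0
    seed: int = 0
    stages: list[str] | None = None

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
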