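"""Run configuration: every tunable threshold, window and seed in one
serializable place.

``siscan`` and ``bootscan`` ship disabled in the default method list:
they are orders of magnitude slower per triplet than the other four and
serve best as confirmatory checks on candidate triplets; enabling them
is a one-line config change.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunConfig", "KNOWN_METHODS"]

KNOWN_METHODS = ["rdp", "maxchi", "chimaera", "threeseq", "siscan", "bootscan"]


@dataclass
class RunConfig:
    # global
    seed: int = 0
    alpha: float = 0.05
    enabled_methods: list[str] = field(
        default_factory=lambda: ["rdp", "maxchi", "chimaera", "threeseq"])
    # rdp
    rdp_window: int = 30              # view columns
    rdp_step: int = 1
    # maxchi / chimaera (variable / informative sites per frame half)
    maxchi_window: int = 35
    maxchi_permutations: int = 500
    chimaera_window: int = 35
    chimaera_permutations: int = 500
    # siscan
    siscan_window: int = 100          # view columns
    siscan_step: int = 20
    siscan_randomizations: int = 500
    siscan_z_threshold: float = 3.0
    # bootscan
    bootscan_window: int = 200        # view columns
    bootscan_step: int = 20
    bootscan_bootstraps: int = 100
    bootscan_support: float = 0.7
    # 3seq
    threeseq_permutations: int = 1000
    # recombinant identification
    tie_margin: float = 0.05
    # consolidation
    overlap_frac: float = 0.5         # Jaccard on regions
    parent_cluster_jc: float = 0.05   # single-linkage donor compatibility
    max_iterations: int = 100
    # breakpoint HMM
    switch_prob: float = 0.01
    emission_error: float = 0.05
    hpd_level: float = 0.95
    # compatibility matrices
    compat_window: int = 500
    compat_step: int = 100
    n_rell: int = 200

    def __post_init__(self) -> None:
        unknown = [m for m in self.enabled_methods if m not in KNOWN_METHODS]
        if unknown:
            raise ValueError(f"unknown methods: {unknown}")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**data)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
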