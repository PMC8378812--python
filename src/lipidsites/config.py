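"""Pipeline configuration: one object holding every stage parameter.

Defaults are the analysis conventions used throughout the package
(0.6 nm contact cutoff, 0.55/1.0 nm dual cutoff, 10 ns residence filter,
10 % residue-occupancy floor, 0.8 nm basic adjacency). The config
round-trips through YAML and hashes stably, so every output file can name
the exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # inputs
    structure: str | None = None
    trajectory: str | None = None
    stride: int = 1
    dt_ns: float | None = None
    lipid_type: str = "CDL"
    # contacts stage
    contact_cutoff: float = 0.6
    skip_fraction: float = 0.1
    min_contact_probability: float = 0.10
    z_bin_width: float = 0.1
    z_profile_residues: tuple[str, ...] = ("ARG", "LYS")
    # sites stage
    lower_cutoff: float = 0.55
    upper_cutoff: float = 1.0
    min_residence_ns: float = 10.0
    residue_occupancy_floor: float = 0.10
    edge_weight_threshold: float = 0.3
    residence_estimator: str = "mean"  # or "survival-fit"
    # annotate stage
    adjacency_cutoff: float = 0.8
    ttest: str = "welch"  # or "pooled"
    adjust: str | None = None  # "bh" for Benjamini-Hochberg
    # rules stage
    rule_z_tolerance: float = 0.3
    rule_depth_center: float = 1.8
    rule_depth_halfwidth: float = 0.5
    rule_aromatic_margin: float = 0.2
    rule_expansion_radius: float = 1.0
    rule_include_tyr: bool = True
    membrane_center_z: float = 0.0
    # determinism
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["z_profile_residues"] = list(self.z_profile_residues)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "z_profile_residues" in d and d["z_profile_residues"] is not None:
            d["z_profile_residues"] = tuple(d["z_profile_residues"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
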