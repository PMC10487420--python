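"""Declarative run configuration with YAML round trip.

Every design-decision toggle is surfaced here so a run's deviations from the
defaults are recorded in its outputs; reports carry the config hash.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .anneal import MoveSet, Schedule
from .energy import NOEParams, Weights
from .errors import ConfigError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    structure: str = ""
    noe_table: str = ""
    dihedral_table: str = ""
    stap_tables: list[str] = field(default_factory=list)  # empty -> analytic prior
    output_dir: str = "noesa_out"
    seed: int = 0
    weights: Weights = field(default_factory=Weights)
    noe_params: NOEParams = field(default_factory=NOEParams)
    schedule: Schedule = field(default_factory=Schedule)
    moveset: MoveSet = field(default_factory=MoveSet)
    # design-decision toggles
    dedup_mode: str = "tightest"  # tightest | first | error
    classify_mode: str = "min"  # min | max pair separation for ambiguous NOEs
    min_models: int = 10
    min_residues: int = 20
    strict_entry_filter: bool = True
    disulfide_cutoff: float = 2.5
    per_model_stats: bool = False
    rms_violated_only: bool = False
    rama_threshold: float = 4.0
    binding_cutoff: float = 4.5
    clash_overlap: float = 0.4

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            for key, typ in (("weights", Weights), ("noe_params", NOEParams),
                             ("schedule", Schedule), ("moveset", MoveSet)):
                if key in d and isinstance(d[key], dict):
                    d[key] = typ(**d[key])
            return cls(**d)
        except (TypeError, ValueError) as e:
            raise ConfigError(str(e)) from None

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
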