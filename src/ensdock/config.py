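"""Pipeline configuration: every threshold of the analysis lives in one place.

Defaults reflect the study conditions the pipeline implements: 2.5 A
invariant-region and shared-pose thresholds, 2.0 A redundancy threshold with
a 5000-pose cap, top-10 retention per search, a 33.0 A search sphere around
the NBD1 center, and 10/12 A switching/cutoff for nonbonded energies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class EnsembleSpec:
    """Input paths and snapshot selection for one conformer ensemble."""

    parent: str
    minimized: str | None = None
    frames_manifest: str | None = None  # TSV: time_ns <tab> path
    start_ns: float = 1.0
    interval_ns: float = 1.0
    count: int = 0


@dataclass
class PipelineConfig:
    # inputs (paths relative to the config file's directory)
    regions: str = "regions.yaml"
    params: str = "params.tsv"
    ligands_dir: str = "ligands"
    deck_pattern: str = "decks/{ligand}__{ensemble}__{conformer}.sdf"
    ensembles: dict[str, EnsembleSpec] = field(default_factory=dict)
    ligand_ids: list[str] = field(default_factory=list)
    analog_id: str = ""
    tautomer_ids: list[str] = field(default_factory=list)
    consensus_states: list[str] = field(default_factory=lambda: ["closed", "open"])
    reference_state: str = "closed"
    fit_region: str = "NBD1"
    electrophile_atoms: list[int] = field(default_factory=list)

    # thresholds (Angstroms unless noted)
    invariance_threshold: float = 2.5
    share_threshold: float = 2.5
    cross_ligand_threshold: float = 2.5
    redundancy_threshold: float = 2.0
    pose_cap: int = 5000
    top_k: int = 10
    search_radius: float = 33.0
    switch_on: float = 10.0
    cutoff: float = 12.0
    contact_cutoff: float = 4.0
    nucleophile_cutoff: float = 5.0
    r_max: float = 2.0
    norm_floor: float = 0.05
    dielectric: float = 1.0
    score_direction: str = "lower"  # engine convention: lower = better
    score_field: str = "SCORE"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "invariance_threshold", "share_threshold", "cross_ligand_threshold",
            "redundancy_threshold", "search_radius", "switch_on", "cutoff",
            "contact_cutoff", "nucleophile_cutoff", "r_max",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.pose_cap < 1 or self.top_k < 1:
            raise ConfigError("pose_cap and top_k must be >= 1")
        if self.score_direction not in ("lower", "higher"):
            raise ConfigError("score_direction must be 'lower' or 'higher'")
        self.ensembles = {
            k: (v if isinstance(v, EnsembleSpec) else EnsembleSpec(**v))
            for k, v in self.ensembles.items()
        }

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def digest(self) -> str:
        """Stable hash of the resolved configuration."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
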