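"""Run configuration: every threshold the pipeline uses, in one place.

The literature this pipeline operationalizes identifies interfaces, cores and
"adjacency" by inspection; the cutoffs below are the package's explicit,
overridable rendering of those calls.  A config serializes losslessly to YAML
so a report can embed the exact parameter set that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # geometric detection cutoffs, Å / degrees
    interface_contact: float = 5.0
    hbond_max_distance: float = 3.5
    hbond_min_angle_with_h: float = 120.0
    hbond_min_base_angle: float = 90.0
    sg_cutoff: float = 2.5
    # burial / exposure
    rsa_core_threshold: float = 0.10
    min_exposed_rsa: float = 0.2
    sequon_max_distance: float = 10.0
    # SASA
    probe_radius: float = 1.4
    sasa_points: int = 960
    # superposition
    prune_cutoff: float = 2.0
    prune_max_iter: int = 20
    # residue ranges per subunit (author numbering), e.g. {"alpha1": [1, 274]}
    regions: dict = field(default_factory=dict)
    # per-chain numbering offsets reconciling isoform numbering differences
    numbering_offsets: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "interface_contact", "hbond_max_distance", "sg_cutoff",
            "sequon_max_distance", "probe_radius", "prune_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def digest(self) -> str:
        """Stable hash of the full parameter set, for report provenance."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
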