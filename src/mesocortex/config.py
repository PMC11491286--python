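"""Run configuration: one serializable object covering a full workflow run.

Every run writes its resolved configuration next to its outputs so any
artifact can be regenerated bit-identically. Per-stage seeds are derived
from the master seed by stable hashing of the stage name, so adding stages
never shifts the seeds of existing ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import yaml

__all__ = ["RunConfig", "derive_seed"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed (< 2^31) from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclasses.dataclass
class RunConfig:
    """All knobs of an end-to-end run.

    Anatomy comes either from CSV files (``anatomy_files`` mapping the loader
    keys to paths) or from the synthetic generator (``synthetic = True``).
    """

    # anatomy source
    synthetic: bool = True
    n_areas: int = 34
    anatomy_files: dict[str, str] = dataclasses.field(default_factory=dict)
    constants_override: dict[str, float] = dataclasses.field(default_factory=dict)
    # simulator
    chi: float = 1.0
    chi_i: float = 2.0
    scale: float = 0.005
    duration: float = 10_000.0
    dt: float = 0.1
    master_seed: int = 1
    strict_eta: bool = False
    # analysis
    transient: float = 2500.0
    corr_bin_ms: float = 1.0
    lvr_refractoriness: float = 5.0
    min_rate_filter: float = 0.5
    min_spikes_filter: int = 10
    # output
    output_dir: str = "runs/default"

    def seed_for(self, stage: str) -> int:
        return derive_seed(self.master_seed, stage)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
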