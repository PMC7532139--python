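"""Run configuration: one object every pipeline stage reads its
parameters from; a serialized copy lands in every output directory."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # synthetic study
    n_participants: int = 12
    n_networks: int = 8
    nodes_per_network: int = 5
    timepoints_per_half: int = 400
    base_within: float = 0.4
    base_between: float = 0.1
    ar_coefficient: float = 0.4
    participant_jitter: float = 0.05
    effect: str = "drug"          # "drug" (default drug-first shift) or "null"
    # measures
    measures: tuple[str, ...] = ("sfc", "dfc", "efc")
    entropy_bins: int = 60
    entropy_range: str = "data"   # "data" or "fixed"
    # statistics
    alpha: float = 0.05
    # classifier
    n_components: int = 3
    sweep: bool = True
    # reproducibility
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in asdict(self).items()}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "measures" in raw:
            raw["measures"] = tuple(raw["measures"])
        return cls(**raw)
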