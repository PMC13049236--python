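"""Run configuration: YAML-backed, validated, written beside every output."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .capnography import FilterSpec
from .cvr_mapping import LagSearchSpec
from .synthetic import ProtocolSpec


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run.

    Unknown keys in the YAML are rejected (typo protection); nested specs
    are validated by their own dataclasses.
    """

    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    filter: FilterSpec = field(default_factory=FilterSpec)
    lag_search: LagSearchSpec = field(default_factory=LagSearchSpec)
    baseline_window: float = 50.0
    petco2_shift: float = 0.0
    min_prominence: float = 5.0
    min_separation: float = 2.0
    frame_order: str = "tag_first"
    z_threshold: float = 2.0
    z_confidence_convention: str = "se"  # "se": z = beta/SE; "ci": beta/CI half-width
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_order not in ("tag_first", "control_first"):
            raise ValueError("frame_order must be 'tag_first' or 'control_first'")
        if self.z_confidence_convention not in ("se", "ci"):
            raise ValueError("z_confidence_convention must be 'se' or 'ci'")

    @property
    def band_mhz(self) -> tuple[float, float]:
        """Pass-band edges in mHz, rounded as conventionally printed."""
        return self.filter.band_mhz

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name: f for f in fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        nested = {"protocol": ProtocolSpec, "filter": FilterSpec, "lag_search": LagSearchSpec}
        kwargs = {}
        for k, v in data.items():
            if k in nested and isinstance(v, dict):
                sub_known = {f.name for f in fields(nested[k])}
                bad = set(v) - sub_known
                if bad:
                    raise ValueError(f"unknown config keys in {k}: {sorted(bad)}")
                kwargs[k] = nested[k](**v)
            else:
                kwargs[k] = v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def write(self, path: str | Path) -> None:
        """Write the resolved configuration beside the outputs."""
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
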