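"""Pipeline configuration: nested sections, YAML loading, config hashing.

Unknown keys are rejected so a typo never silently falls back to a
default; every CLI run logs the fully-resolved configuration and stamps
output tables with its hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .insilico_pcr import PcrConfig
from .locus_filter import FilterConfig
from .primer_design import DesignConstraints

__all__ = ["ScanConfig", "ClusterConfig", "PipelineConfig"]


@dataclass
class ScanConfig:
    min_units: int = 4  # lenient at scan time; the >=6-unit rule is a filter


@dataclass
class ClusterConfig:
    anchor_k: int = 12
    min_flank: int = 20
    max_mismatch: int = 2
    min_support: int = 2


@dataclass
class PipelineConfig:
    seed: int = 0
    scan: ScanConfig = field(default_factory=ScanConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    primer: DesignConstraints = field(default_factory=DesignConstraints)
    ipcress: PcrConfig = field(default_factory=PcrConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sections = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(sections)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, value in data.items():
            f = sections[name]
            if dataclasses.is_dataclass(f.type) or name in (
                "scan",
                "cluster",
                "filter",
                "primer",
                "ipcress",
            ):
                section_cls = {
                    "scan": ScanConfig,
                    "cluster": ClusterConfig,
                    "filter": FilterConfig,
                    "primer": DesignConstraints,
                    "ipcress": PcrConfig,
                }[name]
                valid = {sf.name for sf in dataclasses.fields(section_cls)}
                bad = set(value) - valid
                if bad:
                    raise ValueError(f"unknown keys in config section {name!r}: {sorted(bad)}")
                kwargs[name] = section_cls(**value)
            else:
                kwargs[name] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return clean(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]
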