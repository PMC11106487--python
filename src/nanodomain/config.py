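"""Run configuration and condition manifests.

A run configuration is a single YAML file with sections per stage; unknown
keys are rejected so typos fail loudly.  Every stochastic stage requires an
explicit seed — there are no silent defaults for randomness.  A condition
manifest maps named experimental conditions (e.g. control, latrunculin,
EGTA) to lists of input files and optional comparison pairs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from .exceptions import ParameterError

__all__ = ["PcstormParams", "NandbParams", "FlimParams", "RunConfig",
           "ConditionManifest", "config_hash"]


def _from_mapping(cls, data: dict, context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ParameterError(f"unknown keys in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class PcstormParams:
    bin_nm: float = 10.0
    r_max_nm: float = 500.0
    grid_nm: float = 10.0
    fit_min_nm: float = 10.0
    fit_max_nm: float = 500.0
    sigma_mode: str = "per-roi"
    pooled_sigma_nm: Optional[float] = None
    ks_alpha: float = 0.05


@dataclass(frozen=True)
class NandbParams:
    detrend_window: int = 10
    photon_counting: bool = True
    gain_s: float = 1.0
    offset: float = 0.0
    sigma0: float = 0.0
    calibration_b: Optional[Tuple[float, float, float]] = None  # mono/di/trimer


@dataclass(frozen=True)
class FlimParams:
    intensity_floor: float = 100.0
    weighting: str = "unweighted"
    alpha: float = 0.05


@dataclass(frozen=True)
class RunConfig:
    seed: int
    output_dir: str = "results"
    pcstorm: PcstormParams = field(default_factory=PcstormParams)
    nandb: NandbParams = field(default_factory=NandbParams)
    flim: FlimParams = field(default_factory=FlimParams)

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "seed" not in data:
            raise ParameterError("config must set an explicit integer seed")
        for name, sub in (("pcstorm", PcstormParams), ("nandb", NandbParams),
                          ("flim", FlimParams)):
            if name in data:
                section = data[name]
                if section is None:
                    section = {}
                if not isinstance(section, dict):
                    raise ParameterError(f"section {name!r} must be a mapping")
                if name == "nandb" and "calibration_b" in section and \
                        section["calibration_b"] is not None:
                    section["calibration_b"] = tuple(section["calibration_b"])
                data[name] = _from_mapping(sub, section, f"config section {name!r}")
        return _from_mapping(cls, data, "config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ParameterError("config file must contain a mapping")
        return cls.from_mapping(data)


def config_hash(config: RunConfig) -> str:
    """Stable short hash identifying a configuration (for output provenance)."""
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class ConditionManifest:
    """Named conditions mapping to input files, plus comparison pairs."""

    conditions: Dict[str, List[str]]
    compare: List[Tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ParameterError("manifest must define at least one condition")
        for name, inputs in self.conditions.items():
            if not inputs:
                raise ParameterError(f"condition {name!r} has no inputs")
        for a, b in self.compare:
            for name in (a, b):
                if name not in self.conditions:
                    raise ParameterError(
                        f"comparison references unknown condition {name!r}"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConditionManifest":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ParameterError("manifest file must contain a mapping")
        unknown = set(data) - {"conditions", "compare"}
        if unknown:
            raise ParameterError(f"unknown keys in manifest: {sorted(unknown)}")
        conditions = data.get("conditions")
        if not isinstance(conditions, dict):
            raise ParameterError("manifest must have a 'conditions' mapping")
        compare = [tuple(pair) for pair in data.get("compare", [])]
        return cls(
            conditions={k: list(v) for k, v in conditions.items()},
            compare=compare,
        )
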