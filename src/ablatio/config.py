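"""Run configuration: nested stage configs, strict loading, seed spawning.

A :class:`RunConfig` bundles one config per pipeline stage plus a single
master seed.  Per-stage seeds are derived from the master seed with a
counter-based scheme (``SeedSequence([master, stage_index])``) so any stage
can be re-run independently and reproducibly.  Configs round-trip losslessly
through YAML/JSON; unknown keys are rejected with their location.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .detection import DetectionConfig
from .synthgen import StackConfig

__all__ = ["RunConfig", "NetworkConfig", "SessionConfig", "load_config",
           "save_config", "stage_seed", "STAGE_ORDER"]

STAGE_ORDER = ("synthgen", "detection", "netmodel", "ablation", "rhythm",
               "topology")


@dataclass
class NetworkConfig:
    n: int = 330
    p: float = 0.125
    weight_scale: float = 1.0
    duration_s: float = 25.0
    dt_ms: float = 0.25


@dataclass
class SessionConfig:
    lesion_interval_s: float = 25.0
    batch_size: int = 10
    success_probability: float = 0.5
    quiescence_s: float = 120.0
    #: fractions of detected targets mapped to no model neuron
    #: (non-rhythmogenic glia / premotor subpopulations)
    f_glia: float = 0.0
    f_premotor: float = 0.0
    max_lesions: int | None = None


@dataclass
class RunConfig:
    seed: int = 0
    synthgen: StackConfig = field(default_factory=StackConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    netmodel: NetworkConfig = field(default_factory=NetworkConfig)
    session: SessionConfig = field(default_factory=SessionConfig)


def stage_seed(master_seed: int, stage: str) -> int:
    """Derived seed for a stage; counter-based so stages are independent.
    Always below 2**31."""
    if stage not in STAGE_ORDER:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(master_seed), STAGE_ORDER.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _from_dict(cls, data: dict, location: str):
    if not isinstance(data, dict):
        raise ValueError(f"{location}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(
            f"{location}: unknown key(s) {sorted(unknown)}; "
            f"allowed: {sorted(fields)}")
    kwargs = {}
    for key, value in data.items():
        ftype = fields[key].type
        sub = {"synthgen": StackConfig, "detection": DetectionConfig,
               "netmodel": NetworkConfig, "session": SessionConfig}.get(key)
        if sub is not None:
            kwargs[key] = _from_dict(sub, value, f"{location}.{key}")
        elif isinstance(value, list) and key in ("count_range", "soma_radius_um",
                                                 "area_range_um2"):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML or JSON; an empty file yields all defaults;
    unknown keys raise with their dotted location."""
    with open(path) as fh:
        text = fh.read()
    data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text or "{}")
    if data is None:
        return RunConfig()
    return _from_dict(RunConfig, data, "config")


def save_config(config: RunConfig, path):
    data = asdict(config)
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)
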