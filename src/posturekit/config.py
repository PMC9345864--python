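"""Run configuration: weights, cut-offs, mappings, defaults.

A config file is YAML mirroring :class:`RunConfig`; every field is
optional and defaults reproduce the published constants, e.g.::

    weights: {w1: 0.132, w2: 0.126, w3: 0.165, w4: 0.113, w5: 0.067, w7: 0.400}
    cutoffs: [12.96, 20.14]
    window_policy: relaxed
    joint_map: {C7: SpineShoulder}
    noise_sd: 0.005
    seed: 0
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import WINDOW_POLICIES
from .index import DEFAULT_CUTOFFS, IPAWeights
from .io import DEFAULT_JOINT_MAP
from .session import LANDMARKS
from .simulate import DEFAULT_NOISE_SD


@dataclass(frozen=True)
class RunConfig:
    weights: IPAWeights = field(default_factory=IPAWeights)
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS
    window_policy: str = "relaxed"
    joint_map: dict = field(default_factory=dict)
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self):
        if self.window_policy not in WINDOW_POLICIES:
            raise ValueError(f"window_policy must be one of {WINDOW_POLICIES}")
        lo, hi = self.cutoffs
        if lo <= 0 or hi <= 0:
            raise ValueError("cut-offs must be positive")
        for landmark in self.joint_map:
            if landmark not in LANDMARKS or landmark not in DEFAULT_JOINT_MAP:
                raise ValueError(
                    f"joint_map key {landmark!r} is not a remappable landmark "
                    f"(choose from {tuple(DEFAULT_JOINT_MAP)})"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["weights"] = dataclasses.asdict(self.weights)
        d["cutoffs"] = list(self.cutoffs)
        return d

    def digest(self) -> str:
        """Short stable hash of the configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path=None) -> RunConfig:
    """Load a YAML config file; ``None`` gives the defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    kwargs: dict = {}
    if "weights" in raw:
        kwargs["weights"] = IPAWeights(**raw["weights"])
    if "cutoffs" in raw:
        kwargs["cutoffs"] = tuple(float(c) for c in raw["cutoffs"])
    for key in ("window_policy", "joint_map", "noise_sd", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    unknown = set(raw) - {"weights", "cutoffs", "window_policy", "joint_map", "noise_sd", "seed"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**kwargs)
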