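"""Run configuration: declarative, serialized alongside outputs, reproducible.

One master seed fans out to per-module seeds through ``numpy.random
.SeedSequence`` with fixed child indices, so each stage is independently
reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

#: Fixed child-stream indices for the seed fan-out.
SEED_STREAMS = {
    "behavior": 0,
    "trajectories": 1,
    "epochs": 2,
    "bayes": 3,
    "metacog": 4,
}


@dataclass
class RunConfig:
    mode: str = "synthetic"                 # synthetic | real
    seed: int = 0
    output_dir: str = "results"

    # cohort
    n_group_a: int = 19
    n_group_b: int = 14
    trials_per_participant: int = 300

    # observers (group a = control, group b = ssd)
    coupling_a: float = -0.04
    coupling_b: float = -0.01
    confidence_noise_sd: float = 12.0

    # epochs
    channels: list[str] = field(default_factory=list)  # empty -> full ROI+extras
    fs: float = 128.0
    epoch_window: tuple[float, float] = (-1.0, 2.0)
    pink_sd: float = 2.0
    white_sd: float = 1.5
    intercept_sd: float = 1.0
    erp_gain_scale: float = 1.0   # 0 -> null (no injected effects)

    # statistics
    alpha: float = 0.05
    scan_window: tuple[float, float] = (0.0, 0.5)
    cluster_window: tuple[float, float] = (-0.2, 0.75)
    terms: list[str] = field(default_factory=lambda: ["correctness", "z_confidence", "z_movementRT"])

    # bayes
    n_chains: int = 4
    n_iter: int = 2000
    n_warmup: int = 1000

    # real mode inputs
    edf_paths: list[str] = field(default_factory=list)
    trial_table_path: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        if isinstance(self.epoch_window, list):
            self.epoch_window = tuple(self.epoch_window)
        if isinstance(self.cluster_window, list):
            self.cluster_window = tuple(self.cluster_window)
        if isinstance(self.scan_window, list):
            self.scan_window = tuple(self.scan_window)

    # -- seeds --------------------------------------------------------------
    def module_seed(self, module: str) -> int:
        ss = np.random.SeedSequence(self.seed, spawn_key=(SEED_STREAMS[module],))
        return int(ss.generate_state(1)[0])

    def module_rng(self, module: str) -> np.random.Generator:
        return np.random.default_rng(self.module_seed(module))

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            payload = yaml.safe_load(f) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    @property
    def config_hash(self) -> str:
        return hashlib.sha1(self.to_yaml().encode()).hexdigest()[:12]
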