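"""Run configuration: a small YAML-serializable record driving every verb.

A single master seed is recorded; per-ROI and per-stage random streams
are derived from it with ``numpy.random.SeedSequence``, so adding ROIs
to a batch never perturbs existing ones and re-running a config
reproduces byte-identical table bodies.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .io import config_hash

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    protocol: str = "glioma"
    batch_size: int = 72
    grid_shape: tuple[int, int, int] = (60, 60, 4)
    include_fluid: bool = True
    seed: int = 0
    alpha: float = 0.01
    n_tests_total: int | None = None
    output_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.protocol not in ("glioma", "prostate"):
            raise ValueError("protocol must be 'glioma' or 'prostate'")
        self.grid_shape = tuple(int(x) for x in self.grid_shape)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())

    def provenance(self, version: str) -> dict:
        return {"tool_version": version, "master_seed": self.seed,
                "config_hash": self.hash, "protocol": self.protocol}


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    return RunConfig(**data)
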