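"""Run configuration with YAML round-trip and derived sub-seeds."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .cascade import TuningConfig
from .preprocess import PreprocessConfig
from .tiling import LevelConfig

__all__ = ["RunConfig"]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    levels: tuple[LevelConfig, ...] = (LevelConfig(100), LevelConfig(75), LevelConfig(50))
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    tuning: TuningConfig = dataclasses.field(default_factory=TuningConfig)
    tie_break: str = "low"
    benign_threshold: float = 0.005
    routing: str = "argmax"
    backend: str = "tiny_cnn"  # or "oracle"
    seed: int = 0

    def validate(self) -> None:
        for lv in self.levels:
            lv.validate()
        self.preprocess.validate()
        self.tuning.validate()
        if self.tie_break not in ("low", "high"):
            raise ValueError("tie_break must be 'low' or 'high'")
        if self.backend not in ("tiny_cnn", "oracle"):
            raise ValueError("backend must be 'tiny_cnn' or 'oracle'")

    def sub_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        digest = int(np.random.default_rng(
            [self.seed, *(ord(c) for c in stage)]
        ).integers(2**31))
        return digest

    def to_dict(self) -> dict:
        return {
            "levels": [dataclasses.asdict(lv) for lv in self.levels],
            "preprocess": dataclasses.asdict(self.preprocess),
            "tuning": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self.tuning).items()
            },
            "tie_break": self.tie_break,
            "benign_threshold": self.benign_threshold,
            "routing": self.routing,
            "backend": self.backend,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        levels = tuple(LevelConfig(**lv) for lv in d.get("levels", [])) or cls().levels
        tuning_d = dict(d.get("tuning", {}))
        for key in ("lr_range", "dropout_range", "fc_choices", "batch_choices"):
            if key in tuning_d:
                tuning_d[key] = tuple(tuning_d[key])
        if "filter_choices" in tuning_d:
            tuning_d["filter_choices"] = tuple(tuple(f) for f in tuning_d["filter_choices"])
        return cls(
            levels=levels,
            preprocess=PreprocessConfig(**d.get("preprocess", {})),
            tuning=TuningConfig(**tuning_d),
            tie_break=d.get("tie_break", "low"),
            benign_threshold=d.get("benign_threshold", 0.005),
            routing=d.get("routing", "argmax"),
            backend=d.get("backend", "tiny_cnn"),
            seed=d.get("seed", 0),
        )

    def save(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: Path | str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
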