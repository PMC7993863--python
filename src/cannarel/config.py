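"""Run configuration: one validated schema tying the modules together.

A run is reproducible from a single top-level seed; each stage derives its
own seed by a fixed offset so pipelines re-run identically from one flag.
Unknown keys are rejected so config typos fail loudly.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

SEED_OFFSETS = {"generator": 1, "model": 2, "training": 3}


class GeneratorBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_records: int = 800
    class_weights: tuple[float, float, float, float] = (3243.0, 707.0, 158.0, 1777.0)
    misspelling_rate: float = 0.1
    distractor_rate: float = 0.2


class ModelBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    variant: str = "full"
    word_dim: int = 24
    position_dim: int = 8
    features_per_window: int = 24
    attention_dim: int = 16
    encoder_profile: str = "small"  # "small" or "default"
    dropout: float = 0.3


class TrainingBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    optimizer: str = "adam"
    learning_rate: float = 0.001
    epochs: int = 20
    batch_size: int = 16
    folds: int = 5
    max_dist: float = 0.2


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    lexicon_path: str | None = None
    output_dir: str = "runs"
    generator: GeneratorBlock = GeneratorBlock()
    model: ModelBlock = ModelBlock()
    training: TrainingBlock = TrainingBlock()

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = path.read_text(encoding="utf-8")
        data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.model_validate(data or {})

    def stage_seed(self, stage: str) -> int:
        return (self.seed + SEED_OFFSETS[stage]) % (2**31)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.model_dump(), indent=2, sort_keys=True), encoding="utf-8"
        )
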