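"""Experiment configuration: one JSON file describes one runnable experiment.

All defaults are materialized when a config is saved, so a saved file is a
complete, self-describing record of the run conditions; unknown keys are
rejected by name, and every field is schema-validated.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .dynamics import LoopParams
from .engine import EngineConfig
from .scene import Scene
from .sensor import SensorConfig


class AnalysisConfig(BaseModel):
    """Percept-extraction settings."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    residual_tolerance: float = Field(0.05, gt=0.0)
    c_d: float = Field(0.9, gt=0.0, lt=1.0, description="decision threshold on C_j")
    sigma_dyn: float = Field(0.05, gt=0.0)
    sigma_ret: float = Field(0.25, gt=0.0)
    refine_decode: bool = True
    min_dwell_s: float = Field(0.3, gt=0.0)
    flatness_deg_s2: float = Field(5.0, gt=0.0)


class ExperimentConfig(BaseModel):
    """Scene + sensor + loop + engine + analysis: a complete experiment."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    scene: Scene = Scene(gamma=0.5, mean_luminance=0.5)
    sensor: SensorConfig = SensorConfig()
    params: LoopParams = LoopParams()
    engine: EngineConfig = EngineConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    mode: str = Field("sensor", pattern="^(ideal|sensor|replay)$")
    #: path of a previously recorded trajectory CSV, for replay mode
    replay_source: str | None = None
    seed: int = 0
    out_dir: str = "."

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> ExperimentConfig:
    """Load and schema-validate an experiment config from JSON."""
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    return ExperimentConfig(**data)


def save_config(cfg: ExperimentConfig, path) -> None:
    """Write the config with every default materialized."""
    Path(path).write_text(json.dumps(cfg.model_dump(mode="json"), indent=2) + "\n")
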