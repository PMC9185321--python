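"""Run configuration: schema-validated YAML with desk/paper presets.

The ``desk`` preset is the test-scale default (64 x 64 frames, tiny
networks, short schedule); the ``paper`` preset carries the full-scale
settings (256 x 256 inputs, 70-pixel discriminator patches, batch 7,
initial learning rate 1e-4 decaying tenfold every 70,000 iterations).
Unknown keys are rejected and all violations are reported together.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PreprocessSection(_Section):
    target_size: int = Field(64, ge=16)
    invalid_value: float = 0.0
    fill_max_iters: int = Field(100, ge=1)
    source_range: Optional[tuple[float, float]] = None
    fill_enabled: bool = True


class ModelSection(_Section):
    frames_in: Literal[8] = 8
    frames_out: Literal[8] = 8
    base_channels: int = Field(16, ge=1)
    depth: int = Field(3, ge=2)
    latent_dim: int = Field(64, ge=8)


class DiscriminatorSection(_Section):
    patch_receptive_field: int = Field(34, ge=16)
    base_channels: int = Field(16, ge=1)


class LossSection(_Section):
    w_l2: float = Field(1.0, ge=0)
    w_gradient: float = Field(1.0, ge=0)
    w_flow: float = Field(2.0, ge=0)
    w_adversarial: float = Field(0.05, ge=0)
    flow_norm: Literal["l1", "l2"] = "l1"

    @model_validator(mode="after")
    def _some_weight(self):
        if self.w_l2 == self.w_gradient == self.w_flow == self.w_adversarial == 0:
            raise ValueError("at least one loss weight must be positive")
        return self


class TrainSection(_Section):
    batch_size: int = Field(4, ge=1)
    lr_initial: float = Field(1e-3, gt=0)
    lr_decay_factor: float = Field(0.1, gt=0, le=1)
    lr_decay_every: int = Field(1000, ge=1)
    max_iterations: int = Field(450, ge=0)
    seed: int = 0
    d_steps_per_g_step: int = Field(1, ge=1)
    flow_pairs: int = Field(2, ge=0, le=4)
    flow_iters: int = Field(15, ge=1)
    checkpoint_every: int = Field(0, ge=0)
    log_every: int = Field(10, ge=1)


class ScoreSection(_Section):
    inference_stride: int = Field(1, ge=1)  # 3 for real-time use; 1 for evaluation
    mode: Literal["online", "offline"] = "offline"


class EvalSection(_Section):
    mode: Literal["online", "offline"] = "offline"
    threshold: Optional[float] = None
    threshold_grid: list[float] = Field(
        default_factory=lambda: [round(0.05 * i, 2) for i in range(1, 20)]
    )
    threshold_objective: Literal["youden", "normal_quantile"] = "youden"


class SynthSection(_Section):
    n_train_clips: int = Field(24, ge=1)
    n_test_normal: int = Field(8, ge=1)
    n_test_fall: int = Field(8, ge=1)
    n_frames: int = Field(40, ge=12)
    frame_size: int = Field(64, ge=16)
    p_hole: float = Field(0.05, ge=0, le=0.3)
    jitter_sigma: float = Field(0.01, ge=0)


class RunConfig(_Section):
    master_seed: int = 0
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    model: ModelSection = Field(default_factory=ModelSection)
    discriminator: DiscriminatorSection = Field(default_factory=DiscriminatorSection)
    loss: LossSection = Field(default_factory=LossSection)
    train: TrainSection = Field(default_factory=TrainSection)
    score: ScoreSection = Field(default_factory=ScoreSection)
    eval: EvalSection = Field(default_factory=EvalSection)
    synth: SynthSection = Field(default_factory=SynthSection)


PRESETS: dict[str, dict] = {
    "desk": {},
    "paper": {
        "preprocess": {"target_size": 256},
        "model": {"base_channels": 64, "depth": 4, "latent_dim": 512},
        "discriminator": {"patch_receptive_field": 70, "base_channels": 64},
        "train": {
            "batch_size": 7,
            "lr_initial": 1e-4,
            "lr_decay_factor": 0.1,
            "lr_decay_every": 70_000,
            "max_iterations": 210_000,
        },
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_preset(name: str) -> RunConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return RunConfig.model_validate(PRESETS[name])


def validate_config(
    path: str | Path | None, preset: str = "desk", overrides: dict | None = None
) -> RunConfig:
    """Parse + schema-check a YAML config (empty/missing file: all defaults).

    The preset supplies the base values; the file and then ``overrides``
    are deep-merged on top.  All schema violations are reported at once.
    """
    data: dict = dict(PRESETS[preset]) if preset in PRESETS else {}
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping; got {type(loaded)}")
        data = _deep_merge(data, loaded)
    if overrides:
        data = _deep_merge(data, overrides)
    return RunConfig.model_validate(data)


def echo_config(config: RunConfig, out_dir: str | Path) -> Path:
    """Write the fully resolved config into an output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "config_resolved.yaml"
    path.write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
    return path
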