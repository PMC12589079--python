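"""Pipeline configuration: nested, validated blocks mirroring each module.

Loaded from YAML or JSON; unknown keys are rejected so typos fail fast at
validation time rather than silently falling back to defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigurationError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticBlock(_Strict):
    image_size: int = 128
    n_normal_train: int = 1500
    n_normal_test: int = 500
    n_stroke_train: int = 1400
    n_stroke_test: int = 400
    brain_axes: tuple[float, float] = (48.0, 40.0)
    background_level: float = 20.0
    brain_level: float = 120.0
    lesion_radius: float = 10.0
    lesion_delta: float = 80.0
    noise_sigma: float = 10.0
    seed: int = 0


class PreprocessBlock(_Strict):
    resize_to: int | None = None  # target square resolution; None = keep as-is
    resize_mapping: str = "scale"
    hist_equalize: bool = False
    balance_mode: str | None = None  # oversample | undersample | over_then_under


class FeaturesBlock(_Strict):
    levels: int = 16
    offset: tuple[int, int] = (0, 1)
    canny_sigma: float = 1.0
    canny_low: float = 0.1
    canny_high: float = 0.3


class TrainBlock(_Strict):
    epochs: int = 50
    learning_rate: float = 0.001
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1.0e-8
    batch_size: int | None = 32
    seed: int = 0
    loss: str = "bce"


class EvaluateBlock(_Strict):
    calibration_bins: int = 10


class PipelineConfig(_Strict):
    run_id: str = "run"
    output_dir: str = "vqstroke_output"
    log_level: str = "INFO"
    synthetic: SyntheticBlock = SyntheticBlock()
    preprocess: PreprocessBlock = PreprocessBlock()
    features: FeaturesBlock = FeaturesBlock()
    train: TrainBlock = TrainBlock()
    evaluate: EvaluateBlock = EvaluateBlock()


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML/JSON config file and apply flat override mappings.

    ``overrides`` is a dict of dotted keys (e.g. ``{"train.seed": 7}``) that
    win over file values.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
    for key, value in (overrides or {}).items():
        parts = key.split(".")
        node = data
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    try:
        return PipelineConfig(**data)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc
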