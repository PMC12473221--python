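"""Model and training configuration with YAML round-trip.

Defaults follow the published hyperparameter setting for the full-scale
model: Adam, learning rate 1e-5, dropout 0.1, batch size 64, 50 epochs,
4 attention layers with 4 heads, residual mixing weight lambda = 0.2, and a
mask-ratio lower bound R = 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["ModelConfig", "TrainConfig", "load_config", "save_config"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Parameters
    ----------
    backbone
        Registered backbone name ("densenet121", "tiny", or "stub").
    input_size
        Side length images are resized to before the backbone.
    labels
        Ordered label vocabulary; its length fixes the number of label
        tokens ``n``.
    heads
        Attention heads per layer (``p``); must divide the feature depth.
    layers
        Number of stacked self-attention layers.
    lam
        Residual mixing weight lambda in z_i = g + lam * r_i.
    dropout
        Dropout rate on attention weights and block outputs (train mode).
    attention_scale
        "sqrt_head" (conventional 1/sqrt(d/p) scaling, default) or
        "literal_d" (divide scores by the full depth d).
    transformer_block
        If True each attention layer is wrapped in a pre-norm transformer
        block (layer norm + feed-forward + skip); off by default, where a
        layer is the bare attention map with dropout.
    """

    backbone: str = "densenet121"
    input_size: int = 448
    labels: list = field(default_factory=list)
    heads: int = 4
    layers: int = 4
    lam: float = 0.2
    dropout: float = 0.1
    attention_scale: str = "sqrt_head"
    transformer_block: bool = False

    @property
    def n(self) -> int:
        return len(self.labels)

    def __post_init__(self):
        if self.layers < 1:
            raise ValueError("need at least one attention layer")
        if not 0.0 <= self.lam:
            raise ValueError("lambda must be non-negative")
        if self.attention_scale not in ("sqrt_head", "literal_d"):
            raise ValueError(f"unknown attention_scale {self.attention_scale!r}")


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-5
    batch_size: int = 64
    epochs: int = 50
    seed: int = 0
    mask_lower_ratio: float = 0.25  # R: lower bound of the masked fraction

    def __post_init__(self):
        if not 0.0 <= self.mask_lower_ratio <= 1.0:
            raise ValueError("mask_lower_ratio must lie in [0, 1]")
        if self.optimizer.lower() not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def load_config(path) -> tuple[ModelConfig, TrainConfig]:
    """Read a YAML file holding ``model:`` and/or ``train:`` sections.

    A flat file with Table-style keys (optimizer, learning_rate, dropout,
    batch_size, epochs, layers, heads, lambda) is also accepted.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "model" in raw or "train" in raw:
        model_raw = dict(raw.get("model", {}))
        train_raw = dict(raw.get("train", {}))
    else:  # flat dialect
        model_keys = {f.name for f in ModelConfig.__dataclass_fields__.values()}
        train_keys = {f.name for f in TrainConfig.__dataclass_fields__.values()}
        model_raw = {k: v for k, v in raw.items() if k in model_keys or k == "lambda"}
        train_raw = {k: v for k, v in raw.items() if k in train_keys}
    if "lambda" in model_raw:
        model_raw["lam"] = model_raw.pop("lambda")
    return ModelConfig(**model_raw), TrainConfig(**train_raw)


def save_config(model_cfg: ModelConfig, train_cfg: TrainConfig, path) -> None:
    doc = {"model": asdict(model_cfg), "train": asdict(train_cfg)}
    doc["model"]["lambda"] = doc["model"].pop("lam")
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
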