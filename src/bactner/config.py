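"""Model and training configuration.

Defaults are the published hyper-parameters of the hybrid model: 300-dim
word embeddings, 25-dim character embeddings with a width-3 convolution of
30 kernels, 25-dim POS and 5-dim dictionary embeddings, a BiLSTM with 100
hidden units per direction, dropout 0.5, Adam at learning rate 0.001 with a
per-epoch decay of 0.9 and early-stopping patience 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["ModelConfig"]


@dataclass
class ModelConfig:
    word_dim: int = 300
    char_dim: int = 25
    pos_dim: int = 25
    dict_dim: int = 5
    filter_size: int = 3
    filter_deep: int = 30
    lstm_hidden: int = 100
    dropout: float = 0.5
    lr: float = 0.001
    decay: float = 0.9
    patience: int = 5
    batch_size: int = 16
    max_epochs: int = 50
    grad_clip: float = 5.0
    tol: float = 1e-4
    seed: int = 0
    freeze_word_embeddings: bool = False
    # "decay" is read as a per-epoch multiplicative learning-rate factor;
    # set decay=1.0 to disable, or adam_beta1 to move it into Adam instead.
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        for name in ("word_dim", "char_dim", "pos_dim", "dict_dim",
                     "filter_size", "filter_deep", "lstm_hidden",
                     "batch_size", "patience", "max_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.filter_size % 2 != 1:
            raise ValueError("filter_size must be odd (same-padding)")

    @property
    def input_dim(self) -> int:
        """Per-token input to the encoder: word + char-CNN + pos + dict."""
        return self.word_dim + self.filter_deep + self.pos_dim + self.dict_dim

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
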