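"""Training configuration: architecture sizes, loss weights, optimisation.

Defaults follow the framework's reference settings: loss weights 0.7/0.8/0.5,
CMD order 5, hidden width 256, learning rate 1e-4, L2 1e-5, batch 32,
100 epochs with early stopping, dropout 0.2, AdamW. `TrainConfig.small()`
is the desk-scale profile used for minutes-scale CPU experiments.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["TrainConfig"]

ABLATION_FLAGS = (
    "no_intra",
    "no_inter",
    "no_recon",
    "no_adaptive_fusion",
    "no_calibration",
    "no_environment",
)


@dataclass(frozen=True)
class TrainConfig:
    # task
    task: str = "classification"
    n_classes: int | None = None  # inferred from the dataset when None

    # architecture (utterance width d_tau; shared width d_s = specific d_u)
    d_utterance: int = 128
    d_shared: int = 128
    d_fused: int = 128
    hidden: int = 256
    calibration_hidden: int = 64
    dropout: float = 0.2

    # losses
    beta1: float = 0.7
    beta2: float = 0.8
    beta3: float = 0.5
    cmd_order: int = 5
    cmd_range_width: float = 1.0
    margin: float = 0.2
    n_positives: int = 4
    n_negatives: int = 4
    positive_window: float = 0.5

    # optimisation
    learning_rate: float = 1e-4
    l2: float = 1e-5
    batch_size: int = 32
    epochs: int = 100
    patience: int = 10
    seed: int = 0
    device: str = "cpu"

    # ablation switches; all False reproduces the full model
    no_intra: bool = False
    no_inter: bool = False
    no_recon: bool = False
    no_adaptive_fusion: bool = False
    no_calibration: bool = False
    no_environment: bool = False

    def __post_init__(self):
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.beta1 < 0 or self.beta2 < 0 or self.beta3 < 0:
            raise ValueError("loss weights must be non-negative")
        if self.cmd_order < 1:
            raise ValueError("cmd_order must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch-level moments)")
        if self.device != "cpu":
            raise ValueError("only cpu execution is supported")

    @classmethod
    def small(cls, **overrides) -> "TrainConfig":
        """Desk-scale profile: narrow widths, faster learning rate."""
        base = dict(
            d_utterance=32,
            d_shared=32,
            d_fused=32,
            hidden=64,
            calibration_hidden=32,
            dropout=0.1,
            learning_rate=1e-3,
            epochs=30,
        )
        base.update(overrides)
        return cls(**base)

    def replace(self, **kw) -> "TrainConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Stable hex digest of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def ablations(self) -> dict[str, bool]:
        return {f: getattr(self, f) for f in ABLATION_FLAGS}
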