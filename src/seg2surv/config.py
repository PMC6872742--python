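"""Pipeline configuration with YAML round-tripping and derived stage seeds."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    One ``seed`` deterministically derives every stage's seed (by hashing
    the stage name against it), so a single integer reproduces the full run.
    """

    out_dir: str = "runs/default"
    n_patients: int = 40
    volume_shape: tuple[int, int, int] = (48, 48, 24)
    roi_shape: tuple[int, int, int] = (48, 48, 24)
    modalities: tuple[str, ...] = ("CT", "PET")
    base_channels: int = 8
    n_levels: int = 4
    epochs: int = 10
    lr: float = 1e-3
    weight_decay: float = 0.0
    n_seg_train: int = 14
    n_seg_val: int = 4
    n_aug: int = 0
    k_range: tuple[int, int] = (2, 10)
    n_init: int = 10
    n_folds: int = 6
    horizon_label: str = "2OS"
    survival_beta0: float = 0.0
    survival_betas: dict = field(default_factory=lambda: {"volume": -2.0, "heterogeneity": -1.2})
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31."""
        return (zlib.crc32(stage.encode()) ^ (self.seed * 2654435761)) % (2**31)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        cfg.volume_shape = tuple(cfg.volume_shape)
        cfg.roi_shape = tuple(cfg.roi_shape)
        cfg.modalities = tuple(cfg.modalities)
        cfg.k_range = tuple(cfg.k_range)
        return cfg
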