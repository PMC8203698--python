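"""Pipeline configuration."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the learning and prediction pipeline.

    ``epsilon`` and ``knn_weight_delta`` default to ``None`` and are then
    resolved at fit time relative to the data scale (1e-3 x median segment
    mean and 1e-6 x median pairwise TPD respectively).
    """

    n_segments: int = 8
    w1: float = 0.7
    w2: float = 0.3
    epsilon: float | None = None
    knn_k: int = 3
    min_cluster_size: int = 5
    smoothing_beta: float = 0.5
    knn_weight_delta: float | None = None

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.smoothing_beta < 0:
            raise ValueError("smoothing_beta must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)
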