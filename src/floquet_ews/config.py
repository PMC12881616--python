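"""Validated analysis configuration for runs driven from files or the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .embedding import EmbeddingConfig

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Embedding geometry, rank policy and detection thresholds for one run.

    The configuration is validated on construction and echoed verbatim (as
    YAML) into every output directory so runs are self-describing.
    """

    m: int = 1
    tau: int = 1
    T_steps: int = 365
    window_len: int = 1095
    stride: int | None = None  # default: window_len // 8
    center: bool = False
    rank: int | str = "auto"
    max_rank: int | None = None
    seasonal_band: float = 0.05
    min_coverage: float = 0.9
    noise_floor: float = 0.3
    threshold: float = 1.0
    persistence: int = 3
    max_jump: float = 0.2
    match_method: str = "greedy"
    max_missing_frac: float = 0.2
    max_gap: int = 2
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.stride is None:
            self.stride = max(1, self.window_len // 8)
        self.validate()

    def validate(self) -> None:
        if self.m < 1 or (self.m > 1 and self.tau < 1):
            raise ValueError("need m >= 1 and tau >= 1 when m > 1")
        if self.T_steps < 1 or self.window_len < self.m or self.stride < 1:
            raise ValueError("invalid window geometry")
        if not (0 <= self.seasonal_band < 1):
            raise ValueError("seasonal_band must lie in [0, 1)")
        if not (0 < self.min_coverage <= 1):
            raise ValueError("min_coverage must lie in (0, 1]")
        if self.persistence < 1:
            raise ValueError("persistence must be >= 1")
        if not (0 <= self.max_missing_frac <= 1):
            raise ValueError("max_missing_frac must lie in [0, 1]")
        if isinstance(self.rank, str) and self.rank != "auto":
            raise ValueError("rank must be an integer or 'auto'")
        if self.match_method not in ("greedy", "optimal"):
            raise ValueError("match_method must be 'greedy' or 'optimal'")

    @property
    def embedding(self) -> EmbeddingConfig:
        return EmbeddingConfig(
            m=self.m,
            tau=self.tau,
            T_steps=self.T_steps,
            window_len=self.window_len,
            stride=self.stride,
            center=self.center,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
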