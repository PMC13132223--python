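"""Pipeline configuration: every stage parameter with validated defaults.

Defaults follow the study's stated operating point: mean-expression filter
at the 0.25 quantile, top-25% variance filter, |r| > 0.8 with q <= 0.05,
Leiden resolution 0.2, 100-tree forests, lasso lambda 0.1, stratified
10-fold CV.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    mean_quantile: float = 0.25
    variance_fraction: float = 0.25
    r_threshold: float = 0.8
    q_threshold: float = 0.05
    resolution: float = 0.2
    min_module_size: int = 10
    conservation_q: float = 0.05
    background: str = "union"  # union | intersection | fixed integer
    pairing: str = "last"
    folds: int = 10
    trees: int = 100
    svm_c: float = 1.0
    lasso_lambda: float = 0.1
    permutation_repeats: int = 10
    combine: str = "mean"  # mean | min | rank-mean
    sweep_grid: list[int] = field(default_factory=lambda: [1, 2, 5, 10, 20, 50])
    seed: int = 42

    def validate(self) -> "PipelineConfig":
        if not 0.0 <= self.mean_quantile < 1.0:
            raise ConfigurationError("mean_quantile must be in [0, 1)")
        if not 0.0 < self.variance_fraction <= 1.0:
            raise ConfigurationError("variance_fraction must be in (0, 1]")
        for name in ("r_threshold", "q_threshold", "conservation_q"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be > 0")
        if self.min_module_size < 1:
            raise ConfigurationError("min_module_size must be >= 1")
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if self.trees < 1 or self.permutation_repeats < 1:
            raise ConfigurationError("trees and permutation_repeats must be >= 1")
        if self.lasso_lambda <= 0 or self.svm_c <= 0:
            raise ConfigurationError("lasso_lambda and svm_c must be > 0")
        if not (
            self.background in ("union", "intersection")
            or isinstance(self.background, int)
        ):
            raise ConfigurationError(
                "background must be 'union', 'intersection', or an integer"
            )
        if self.pairing not in ("last", "first"):
            raise ConfigurationError("pairing must be 'last' or 'first'")
        if self.combine not in ("mean", "min", "rank-mean"):
            raise ConfigurationError("combine must be mean | min | rank-mean")
        if sorted(set(self.sweep_grid)) != list(self.sweep_grid) or (
            self.sweep_grid and self.sweep_grid[0] < 1
        ):
            raise ConfigurationError("sweep_grid must be strictly increasing, >= 1")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
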