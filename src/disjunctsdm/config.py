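"""Pipeline configuration.

Defaults follow the published study design where the study states a value:
10 000 pseudo-absence points, 10 split-sample cross-validation repetitions
holding out 30 %, 100 similarity-test randomizations, background buffers of
5/10/15 km, a >= 50 % majority-consensus ensemble, and all three ROC threshold
rules. ``n_pa_sets`` allows repeating the whole cross-validation over several
independent pseudo-absence draws (so 10 x 10 = 100 runs is expressible).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluation import THRESHOLD_RULES

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value; names the offender."""


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    buffers_km: tuple[float, ...] = (5.0, 10.0, 15.0)
    env_grid_R: int = 100
    n_background: int = 10000
    n_cv: int = 10
    test_frac: float = 0.3
    n_pa_sets: int = 1
    similarity_reps: int = 100
    alpha: float = 0.05
    consensus_fraction: float = 0.5
    threshold_rules: tuple[str, ...] = THRESHOLD_RULES
    occupancy_correction: bool = True
    run_niche_analysis: bool = True
    run_sdm: bool = True
    #: consensus current-climate binaries feed the range-change index
    #: (set False to use the full-data model instead)
    current_consensus: bool = True
    #: file-driven runs (CLI): where scenarios and occurrences live
    scenarios_dir: str | None = None
    occurrences_path: str | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        if self.n_background <= 0 or self.n_cv <= 0 or self.n_pa_sets <= 0:
            raise ConfigError("n_background, n_cv and n_pa_sets must be positive")
        if not (0.0 < self.test_frac < 1.0):
            raise ConfigError(f"test_frac must be in (0, 1), got {self.test_frac}")
        if not (0.0 < self.consensus_fraction <= 1.0):
            raise ConfigError("consensus_fraction must be in (0, 1]")
        if self.similarity_reps < 19:
            raise ConfigError("similarity_reps must be >= 19")
        if any(b <= 0 for b in self.buffers_km):
            raise ConfigError("buffers_km must be positive")
        bad = set(self.threshold_rules) - set(THRESHOLD_RULES)
        if bad:
            raise ConfigError(f"unknown threshold rule(s): {sorted(bad)}")
        if self.env_grid_R < 10:
            raise ConfigError("env_grid_R must be >= 10")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("buffers_km", "threshold_rules"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["buffers_km"] = list(self.buffers_km)
        d["threshold_rules"] = list(self.threshold_rules)
        return d
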