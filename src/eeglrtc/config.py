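"""Pipeline configuration: YAML in, validated dataclasses out.

Unknown keys are rejected so that typos fail loudly before any stage
runs. Defaults mirror the analysis defaults used throughout the
package (0.5-45 Hz band, 128 Hz, 2 s windows at 100 ms, 25 box sizes in
[10, N/4], per-window LDA with 10x10-fold CV).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError
from .synth import SyntheticSpec


def _from_mapping(cls, mapping, where):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ParameterError(f"unknown key(s) {sorted(unknown)} in {where}")
    return cls(**mapping)


@dataclass
class PrepConfig:
    band_low: float = 0.5
    band_high: float = 45.0
    filter_order: int = 4
    resample_to: float = 128.0
    window: float = 2.0
    step: float = 0.1
    taper: str = "hanning"
    alpha_low: float = 8.0
    alpha_high: float = 13.0

    def __post_init__(self):
        if not (0 < self.band_low < self.band_high):
            raise ParameterError("need 0 < band_low < band_high")
        if self.window <= 0 or self.step <= 0:
            raise ParameterError("window and step must be positive")
        if self.taper not in ("hanning", "none"):
            raise ParameterError("taper must be 'hanning' or 'none'")


@dataclass
class DfaConfig:
    n_min: int = 10
    k_sizes: int = 25
    smooth_alpha: float = 0.3
    stitched_lo_s: float = 2.0
    stitched_hi_s: float = 20.0

    def __post_init__(self):
        if not (0 < self.smooth_alpha <= 1):
            raise ParameterError("smooth_alpha must lie in (0, 1]")
        if self.stitched_lo_s >= self.stitched_hi_s:
            raise ParameterError("stitched bounds must be increasing")


@dataclass
class ValidateConfig:
    n_shuffles_per_window: int = 1
    max_windows: int = 60       # cap per run; ARMA searches are costly
    count_d_parameter: bool = False
    arma_method: str = "burg"


@dataclass
class ClassifyConfig:
    folds: int = 10
    reps: int = 10
    alpha: float = 0.05
    scheme: str = "within"      # or "loso"
    use_smoothed: bool = True

    def __post_init__(self):
        if self.scheme not in ("within", "loso"):
            raise ParameterError("scheme must be 'within' or 'loso'")


@dataclass
class StatsConfig:
    alpha: float = 0.05
    test: str | None = None     # None = normality-gated choice per window


@dataclass
class PipelineConfig:
    synth: SyntheticSpec = field(default_factory=SyntheticSpec)
    prep: PrepConfig = field(default_factory=PrepConfig)
    dfa: DfaConfig = field(default_factory=DfaConfig)
    validate: ValidateConfig = field(default_factory=ValidateConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        mapping = dict(mapping or {})
        known = {"synth", "prep", "dfa", "validate", "classify", "stats",
                 "seed"}
        unknown = set(mapping) - known
        if unknown:
            raise ParameterError(f"unknown top-level key(s) {sorted(unknown)}")
        sections = {
            "synth": SyntheticSpec, "prep": PrepConfig, "dfa": DfaConfig,
            "validate": ValidateConfig, "classify": ClassifyConfig,
            "stats": StatsConfig,
        }
        kwargs = {}
        for name, klass in sections.items():
            sub = dict(mapping.get(name, {}))
            if name == "synth" and "channels" in sub:
                sub["channels"] = tuple(sub["channels"])
            kwargs[name] = _from_mapping(klass, sub, f"section '{name}'")
        kwargs["seed"] = int(mapping.get("seed", 0))
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_mapping(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["channels"] = list(self.synth.channels)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()
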