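"""One canonical configuration object driving all pipeline stages.

Sections mirror the stages: [sim], [preprocess], [model], [train], [eval],
[io]. Every tunable decision parameter is surfaced here with its default,
the file round-trips through YAML unchanged, and unknown keys are rejected
so typos fail loudly. CLI flags override file values; the resolved config is
embedded in output artifacts for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields

import yaml

from .model import ModelConfig
from .sim import SimConfig
from .train import TrainConfig

__all__ = ["PreprocessConfig", "EvalConfig", "IOConfig", "PipelineConfig"]


@dataclass
class PreprocessConfig:
    n: int = 60                     # cycles per contextual sample
    min_len_s: float = 480.0        # record-length screen (8 min)
    delta_thresh: float = 10.0      # subject-inclusion ΔSBP (mmHg)
    label_mode: str = "sbp"         # sbp | dbp (label = ABP peak | valley)
    use_true_onsets: bool = False   # simulator-truth bypass, for validation
    ratios: tuple = (7, 1, 2)


@dataclass
class EvalConfig:
    steady_thresh: float = 10.0     # mmHg, steady/unsteady boundary
    beat_window: int = 10           # beats per beat-averaged value


@dataclass
class IOConfig:
    n_subjects: int = 10
    force: bool = False             # allow overwriting outputs


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    io: IOConfig = field(default_factory=IOConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        d = self.to_dict()
        d["sim"]["surge_magnitude_range"] = list(
            d["sim"]["surge_magnitude_range"])
        d["preprocess"]["ratios"] = list(d["preprocess"]["ratios"])
        s = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w") as f:
                f.write(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sections = {f.name: f for f in fields(cls)}
        unknown = set(d) - set(sections)
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        kwargs = {}
        for name, sec in d.items():
            sec_cls = {
                "sim": SimConfig, "preprocess": PreprocessConfig,
                "model": ModelConfig, "train": TrainConfig,
                "eval": EvalConfig, "io": IOConfig,
            }[name]
            valid = {f.name for f in fields(sec_cls)}
            bad = set(sec) - valid
            if bad:
                raise ValueError(
                    f"unknown key(s) in [{name}]: {sorted(bad)}")
            sec = dict(sec)
            if name == "sim" and "surge_magnitude_range" in sec:
                sec["surge_magnitude_range"] = tuple(
                    sec["surge_magnitude_range"])
            if name == "preprocess" and "ratios" in sec:
                sec["ratios"] = tuple(sec["ratios"])
            kwargs[name] = sec_cls(**sec)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})
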