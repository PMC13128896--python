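"""Pipeline configuration: YAML-backed, validated, with seeded stage fan-out."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .attribution import AgeBinScheme
from .model import ModelConfig
from .phases import DEFAULT_SCALES
from .selection import StratumScheme
from .simulate import SimConfig

__all__ = ["PipelineConfig", "derive_seed", "load_pipeline_config"]

STAGES = (
    "simulate",
    "select_features",
    "train",
    "predict",
    "explain",
    "phases",
    "evaluate",
)


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: crc32 of the stage name folded into the
    global seed, so each stage is independently reproducible."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Exactly one of ``synthetic`` (a SimConfig) or ``inputs`` (paths to a beta
    matrix and sample sheet) must be set.
    """

    seed: int = 0
    output_dir: str = "strataclock_run"
    synthetic: SimConfig | None = None
    inputs: dict[str, str] | None = None  # {"beta": ..., "meta": ...}
    stratum_scheme: StratumScheme = field(default_factory=StratumScheme)
    selection_fraction: float = 0.01
    model: ModelConfig = field(default_factory=ModelConfig.test_default)
    always_train: str | None = None
    background_size: int = 100
    attribution_steps: int = 64
    bin_scheme: AgeBinScheme = field(default_factory=AgeBinScheme)
    bootstrap_scales: tuple[float, ...] = DEFAULT_SCALES
    bootstrap_n: int = 200
    cut_k: int | None = 4
    cut_height: float | None = None
    extreme_k: int = 1000
    by_sex_phases: bool = True

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of synthetic or inputs must be set")
        if self.inputs is not None:
            missing = {"beta", "meta"} - set(self.inputs)
            if missing:
                raise ValueError(f"inputs missing keys: {sorted(missing)}")
        if (self.cut_k is None) == (self.cut_height is None):
            raise ValueError("exactly one of cut_k or cut_height must be set")
        if not 0 < self.selection_fraction <= 1:
            raise ValueError("selection_fraction must be in (0, 1]")

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    def to_yaml(self, path: str | Path | None = None) -> str:
        payload: dict[str, Any] = {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "selection_fraction": self.selection_fraction,
            "always_train": self.always_train,
            "background_size": self.background_size,
            "attribution_steps": self.attribution_steps,
            "bootstrap_scales": list(self.bootstrap_scales),
            "bootstrap_n": self.bootstrap_n,
            "cut_k": self.cut_k,
            "cut_height": self.cut_height,
            "extreme_k": self.extreme_k,
            "by_sex_phases": self.by_sex_phases,
            "stratum_scheme": {
                "age_edges": list(self.stratum_scheme.age_edges),
                "by_sex": self.stratum_scheme.by_sex,
            },
            "model": asdict(self.model),
            "bin_scheme": {
                "first_edge": self.bin_scheme.first_edge,
                "width": self.bin_scheme.width,
                "last_edge": self.bin_scheme.last_edge,
            },
        }
        if self.synthetic is not None:
            sim = asdict(self.synthetic)
            sim["age_range"] = list(self.synthetic.age_range)
            sim["phase_boundaries"] = list(self.synthetic.phase_boundaries)
            sim["class_counts"] = dict(self.synthetic.class_counts)
            sim["effect_sizes"] = dict(self.synthetic.effect_sizes)
            payload["synthetic"] = sim
        if self.inputs is not None:
            payload["inputs"] = dict(self.inputs)
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return pipeline_config_from_dict(raw)


def pipeline_config_from_dict(raw: dict[str, Any]) -> PipelineConfig:
    kwargs: dict[str, Any] = {}
    for key in (
        "seed", "output_dir", "selection_fraction", "always_train",
        "background_size", "attribution_steps", "bootstrap_n",
        "cut_k", "cut_height", "extreme_k", "by_sex_phases",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "bootstrap_scales" in raw:
        kwargs["bootstrap_scales"] = tuple(raw["bootstrap_scales"])
    if "stratum_scheme" in raw:
        s = raw["stratum_scheme"]
        kwargs["stratum_scheme"] = StratumScheme(
            age_edges=tuple(s.get("age_edges", (10, 40, 50, 70, 100))),
            by_sex=bool(s.get("by_sex", True)),
        )
    if "model" in raw:
        kwargs["model"] = ModelConfig(**raw["model"])
    if "bin_scheme" in raw:
        kwargs["bin_scheme"] = AgeBinScheme(**raw["bin_scheme"])
    if raw.get("synthetic") is not None:
        sim = dict(raw["synthetic"])
        if "age_range" in sim:
            sim["age_range"] = tuple(sim["age_range"])
        if "phase_boundaries" in sim:
            sim["phase_boundaries"] = tuple(sim["phase_boundaries"])
        kwargs["synthetic"] = SimConfig(**sim)
    if raw.get("inputs") is not None:
        kwargs["inputs"] = dict(raw["inputs"])
    return PipelineConfig(**kwargs)
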