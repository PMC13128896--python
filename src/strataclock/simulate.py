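"""Seeded synthetic methylome cohorts with planted ground truth.

Trajectories are built on the logit scale and passed through the inverse
logit, so every simulated beta lands in [0, 1] without clipping. CpG classes:

* ``linear`` — constant logit slope over the whole age range.
* ``logistic`` — smooth sigmoidal shift centred at a random midlife age.
* ``piecewise_phase`` — level jumps exactly at the configured phase
  boundaries (plus a small common drift), so the slope changes at each
  boundary and age-bin profiles are step-structured.
* ``sex_modulated`` — linear trajectories whose slope depends on sex.
* ``null`` — flat; any apparent age signal is noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .io import BetaMatrix, SampleMeta, SEX_FEMALE, SEX_MALE

__all__ = ["SimConfig", "PlantedTruth", "simulate_cohort", "truth_phase_partition"]

CPG_CLASSES = ("linear", "logistic", "piecewise_phase", "sex_modulated", "null")

DEFAULT_CLASS_COUNTS = {
    "linear": 200,
    "logistic": 100,
    "piecewise_phase": 200,
    "sex_modulated": 100,
    "null": 400,
}

DEFAULT_EFFECT_SIZES = {
    "linear": 1.5,
    "logistic": 1.5,
    "piecewise_phase": 2.0,
    "sex_modulated": 1.5,
}


@dataclass
class SimConfig:
    """Parameters of a synthetic multi-cohort methylome."""

    n_samples_per_cohort: int = 200
    n_cohorts: int = 3
    age_range: tuple[float, float] = (13.0, 100.0)
    sex_ratio: float = 0.5  # fraction male
    class_counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    phase_boundaries: tuple[float, ...] = (35.0, 45.0, 65.0)
    effect_sizes: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    noise_sd: float = 0.3
    cohort_offsets: Sequence[float] | None = None  # logit shifts, default 0.2*index
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range min must be < max, got {self.age_range}")
        unknown = set(self.class_counts) - set(CPG_CLASSES)
        if unknown:
            raise ValueError(f"unknown CpG classes: {sorted(unknown)}")
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        bounds = tuple(self.phase_boundaries)
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("phase_boundaries must be strictly increasing")
        if any(not (lo < b < hi) for b in bounds):
            raise ValueError("phase_boundaries must lie inside age_range")
        if self.n_samples_per_cohort <= 0 or self.n_cohorts <= 0:
            raise ValueError("need at least one cohort with at least one sample")
        if sum(self.class_counts.values()) == 0:
            raise ValueError("need at least one CpG")

    @property
    def n_cpgs(self) -> int:
        return sum(self.class_counts.values())

    def resolved_cohort_offsets(self) -> np.ndarray:
        if self.cohort_offsets is not None:
            offsets = np.asarray(self.cohort_offsets, dtype=float)
            if offsets.size != self.n_cohorts:
                raise ValueError("cohort_offsets length must equal n_cohorts")
            return offsets
        return 0.2 * np.arange(self.n_cohorts, dtype=float)


@dataclass
class PlantedTruth:
    """Ground truth planted into a simulated cohort."""

    class_labels: dict[str, str]  # cpg -> class
    params: dict[str, dict]  # cpg -> trajectory parameters
    noiseless_beta: BetaMatrix
    phase_boundaries: tuple[float, ...]

    def cpgs_of_class(self, cls: str) -> list[str]:
        return [c for c, lab in self.class_labels.items() if lab == cls]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "class_labels": self.class_labels,
            "params": self.params,
            "phase_boundaries": list(self.phase_boundaries),
            "noiseless_beta": {
                "probe_ids": self.noiseless_beta.probe_ids,
                "sample_ids": self.noiseless_beta.sample_ids,
                "values": self.noiseless_beta.values.tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        nb = payload["noiseless_beta"]
        return cls(
            class_labels=payload["class_labels"],
            params=payload["params"],
            noiseless_beta=BetaMatrix(nb["probe_ids"], nb["sample_ids"], np.array(nb["values"])),
            phase_boundaries=tuple(payload["phase_boundaries"]),
        )


def _trajectory_logit(
    cls: str,
    params: dict,
    ages: np.ndarray,
    sexes: np.ndarray,
    age_range: tuple[float, float],
    boundaries: tuple[float, ...],
) -> np.ndarray:
    """Noiseless logit trajectory of one CpG across samples."""
    lo, hi = age_range
    t = (ages - (lo + hi) / 2) / ((hi - lo) / 2)  # normalized age in [-1, 1]
    base = params["baseline"]
    if cls == "linear":
        return base + params["slope"] * t
    if cls == "logistic":
        return base + params["amplitude"] * np.tanh((ages - params["center"]) / params["width"])
    if cls == "piecewise_phase":
        level = np.full_like(ages, base, dtype=float)
        for b, jump in zip(boundaries, params["jumps"]):
            level = level + jump * (ages >= b)
        return level + params["drift"] * t
    if cls == "sex_modulated":
        slope = np.where(sexes == SEX_MALE, params["slope_male"], params["slope_female"])
        return base + slope * t
    if cls == "null":
        return np.full_like(ages, base, dtype=float)
    raise ValueError(f"unknown CpG class {cls!r}")


def _draw_params(cls: str, effect: float, rng: np.random.Generator,
                 age_range: tuple[float, float], n_boundaries: int) -> dict:
    base = float(rng.uniform(-1.5, 1.5))
    sign = float(rng.choice([-1.0, 1.0]))
    if cls == "linear":
        return {"baseline": base, "slope": sign * effect}
    if cls == "logistic":
        lo, hi = age_range
        center = float(rng.uniform(lo + 0.25 * (hi - lo), lo + 0.75 * (hi - lo)))
        return {
            "baseline": base,
            "amplitude": sign * effect,
            "center": center,
            "width": float(rng.uniform(5.0, 12.0)),
        }
    if cls == "piecewise_phase":
        jumps = (rng.choice([-1.0, 1.0], size=n_boundaries) * effect).tolist()
        return {"baseline": base, "jumps": jumps, "drift": sign * 0.15 * effect}
    if cls == "sex_modulated":
        return {
            "baseline": base,
            "slope_male": sign * effect,
            "slope_female": -sign * effect * float(rng.uniform(0.2, 1.0)),
        }
    if cls == "null":
        return {"baseline": base}
    raise ValueError(f"unknown CpG class {cls!r}")


def simulate_cohort(config: SimConfig) -> tuple[BetaMatrix, SampleMeta, PlantedTruth]:
    """Simulate a seeded multi-cohort beta matrix with planted truth.

    Identical configs (including seed) produce bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    n_total = config.n_samples_per_cohort * config.n_cohorts

    sample_ids = [f"S{i:05d}" for i in range(n_total)]
    cohorts = [f"cohort{k}" for k in range(config.n_cohorts) for _ in range(config.n_samples_per_cohort)]
    ages = rng.uniform(lo, hi, size=n_total)
    sexes = np.where(rng.random(n_total) < config.sex_ratio, SEX_MALE, SEX_FEMALE)
    meta = SampleMeta(sample_ids, ages, sexes, cohorts)

    offsets = config.resolved_cohort_offsets()
    offset_per_sample = np.repeat(offsets, config.n_samples_per_cohort)

    probe_ids: list[str] = []
    class_labels: dict[str, str] = {}
    params: dict[str, dict] = {}
    clean_logit = np.empty((config.n_cpgs, n_total))
    i = 0
    for cls in CPG_CLASSES:
        count = int(config.class_counts.get(cls, 0))
        effect = float(config.effect_sizes.get(cls, 0.0))
        for _ in range(count):
            pid = f"cg{i:08d}"
            p = _draw_params(cls, effect, rng, config.age_range, len(config.phase_boundaries))
            probe_ids.append(pid)
            class_labels[pid] = cls
            params[pid] = p
            clean_logit[i] = _trajectory_logit(
                cls, p, ages, sexes, config.age_range, config.phase_boundaries
            )
            i += 1

    mean_logit = clean_logit + offset_per_sample[None, :]
    noiseless = BetaMatrix(list(probe_ids), list(sample_ids), expit(mean_logit))
    noisy_logit = mean_logit + rng.normal(0.0, config.noise_sd, size=mean_logit.shape)
    beta = BetaMatrix(list(probe_ids), list(sample_ids), expit(noisy_logit))

    truth = PlantedTruth(
        class_labels=class_labels,
        params=params,
        noiseless_beta=noiseless,
        phase_boundaries=tuple(config.phase_boundaries),
    )
    return beta, meta, truth


def truth_phase_partition(
    truth: PlantedTruth | Sequence[float],
    bins: Sequence[tuple[float, float]],
) -> list[int]:
    """Label each age bin with the planted phase containing its midpoint.

    ``bins`` are ordered, non-overlapping ``(lo, hi)`` intervals. A bin that
    straddles a boundary is assigned by its midpoint. Phases are numbered from
    1 (below the first boundary) upward; with no boundaries every bin is
    phase 1.
    """
    boundaries = (
        truth.phase_boundaries if isinstance(truth, PlantedTruth) else tuple(truth)
    )
    prev_hi = None
    for lo, hi in bins:
        if hi <= lo:
            raise ValueError(f"bin ({lo}, {hi}) is empty or reversed")
        if prev_hi is not None and lo < prev_hi:
            raise ValueError("bins must be ordered and non-overlapping")
        prev_hi = hi
    labels = []
    for lo, hi in bins:
        mid = (lo + hi) / 2
        phase = 1 + sum(mid >= b for b in boundaries)
        labels.append(phase)
    return labels
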