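"""Gradient-based Shapley attribution and age-bin aggregation.

Attributions use the expected-gradients estimator

    phi_i = E_{x' ~ background, a ~ U(0,1)} [ (x_i - x'_i) * df/dx_i(x' + a(x - x')) ]

evaluated with every background sample weighted equally and a midpoint rule
over ``a``, so a linear model's attributions equal
``w_i * (x_i - mean_background(x_i))`` exactly and the estimator is
deterministic given its settings. Completeness (sum of attributions equals
prediction minus the background mean prediction) holds exactly for linear
models and approximately otherwise.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SampleMeta
from .model import AgeModel, LocoEnsemble

__all__ = [
    "AttributionMatrix",
    "AgeBinScheme",
    "AgeBinProfile",
    "sample_background",
    "explain",
    "bin_profiles",
    "select_extreme_cpgs",
]

logger = logging.getLogger(__name__)

#: finite bounds substituted for the open-ended first and last age bins
AGE_FLOOR = 0.0
AGE_CAP = 120.0


@dataclass
class AttributionMatrix:
    """Samples x features attribution values with estimator provenance."""

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    base_value: float  # mean model output over the background set
    background_ids: list[str]
    n_steps: int
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)

    def completeness_gap(self, predictions: np.ndarray) -> float:
        """Mean |sum(phi) - (f(x) - E[f])| relative to mean |f(x) - E[f]|."""
        offset = np.asarray(predictions, dtype=float) - self.base_value
        gap = np.abs(self.values.sum(axis=1) - offset)
        denom = np.abs(offset).mean()
        return float(gap.mean() / denom) if denom > 0 else float(gap.mean())

    def write(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        frame = self.to_frame()
        frame.index.name = "sample_id"
        frame.to_csv(Path(path), sep="\t")
        if sidecar is not None:
            Path(sidecar).write_text(
                json.dumps(
                    {
                        "base_value": self.base_value,
                        "background_ids": self.background_ids,
                        "n_steps": self.n_steps,
                        "seed": self.seed,
                    }
                )
            )


def sample_background(
    X: pd.DataFrame, size: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Seeded random subsample of (training) rows to act as the background."""
    if size >= len(X):
        return X
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(X), size=size, replace=False)
    return X.iloc[np.sort(idx)]


def explain(
    model: AgeModel | LocoEnsemble,
    X: pd.DataFrame,
    background: pd.DataFrame,
    n_steps: int = 200,
    seed: int | None = None,
) -> AttributionMatrix:
    """Expected-gradients attribution of every sample in ``X``.

    ``n_steps`` is the total number of (background, interpolation) gradient
    evaluations per sample; every background row is used equally often with
    midpoint interpolation coefficients, so the estimate is deterministic.
    LOCO ensembles are explained as the mean of their submodels' attributions
    (gradients of the mean prediction).
    """
    if len(background) == 0:
        raise ValueError("background set must be non-empty")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    models = list(model.submodels.values()) if isinstance(model, LocoEnsemble) else [model]
    models[0].check_contract(X)
    models[0].check_contract(background)

    Xa = X.to_numpy(dtype=float)
    bg = background.to_numpy(dtype=float)
    n_bg = bg.shape[0]
    m_alpha = max(1, math.ceil(n_steps / n_bg))
    alphas = (np.arange(m_alpha) + 0.5) / m_alpha

    phi = np.zeros_like(Xa)
    for b in range(n_bg):
        diff = Xa - bg[b]
        for a in alphas:
            point = bg[b] + a * diff
            grad = np.mean([mdl.input_gradients(point) for mdl in models], axis=0)
            phi += diff * grad
    phi /= n_bg * m_alpha

    base = float(np.mean([mdl.predict_array(bg) for mdl in models]))
    return AttributionMatrix(
        values=phi,
        feature_names=list(X.columns),
        sample_ids=[str(s) for s in X.index],
        base_value=base,
        background_ids=[str(s) for s in background.index],
        n_steps=n_bg * m_alpha,
        seed=seed,
    )


@dataclass(frozen=True)
class AgeBinScheme:
    """Open-ended first and last bins around fixed-width interior bins.

    Default: <20, [20, 25), ..., [80, 85), >=85. Open ends use finite
    stand-in bounds (AGE_FLOOR / AGE_CAP) when a midpoint is needed.
    """

    first_edge: float = 20.0
    width: float = 5.0
    last_edge: float = 85.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.last_edge <= self.first_edge:
            raise ValueError("invalid age-bin scheme")
        span = self.last_edge - self.first_edge
        if abs(span / self.width - round(span / self.width)) > 1e-9:
            raise ValueError("bin width must evenly divide the interior span")

    def intervals(self) -> list[tuple[float, float]]:
        edges = [AGE_FLOOR, *np.arange(self.first_edge, self.last_edge + self.width / 2, self.width), AGE_CAP]
        return [(float(lo), float(hi)) for lo, hi in zip(edges, edges[1:])]

    def labels(self) -> list[str]:
        inner = np.arange(self.first_edge, self.last_edge, self.width)
        return (
            [f"<{self.first_edge:g}"]
            + [f"{lo:g}-{lo + self.width - 1:g}" for lo in inner]
            + [f"{self.last_edge:g}+"]
        )

    def assign(self, ages: np.ndarray) -> np.ndarray:
        """Index of the bin containing each age."""
        ages = np.asarray(ages, dtype=float)
        edges = np.arange(self.first_edge, self.last_edge + self.width / 2, self.width)
        return np.searchsorted(edges, ages, side="right")


@dataclass
class AgeBinProfile:
    """Per-age-bin attribution summaries (signed mean and mean magnitude)."""

    bin_labels: list[str]
    bin_intervals: list[tuple[float, float]]
    feature_names: list[str]
    signed_mean: np.ndarray  # bins x features
    magnitude_mean: np.ndarray  # bins x features
    counts: np.ndarray  # samples per bin

    def __post_init__(self) -> None:
        b, f = len(self.bin_labels), len(self.feature_names)
        if self.signed_mean.shape != (b, f) or self.magnitude_mean.shape != (b, f):
            raise ValueError("profile shapes do not match bins x features")

    def signed_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.signed_mean, index=self.bin_labels, columns=self.feature_names)

    def magnitude_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.magnitude_mean, index=self.bin_labels, columns=self.feature_names)

    def write(self, path: str | Path) -> None:
        signed = self.signed_frame()
        signed.insert(0, "n_samples", self.counts)
        signed.index.name = "age_bin"
        signed.to_csv(Path(path), sep="\t")

    def mean_magnitude(self, drop: Sequence[str] = ()) -> pd.Series:
        """Mean |phi| per feature across bins (unweighted over bins)."""
        frame = self.magnitude_frame().drop(columns=list(drop), errors="ignore")
        return frame.mean(axis=0)


def bin_profiles(
    attr: AttributionMatrix,
    meta: SampleMeta,
    scheme: AgeBinScheme | None = None,
) -> AgeBinProfile:
    """Average attributions within age bins; empty bins are dropped and logged."""
    scheme = scheme or AgeBinScheme()
    if len(meta) == 0:
        raise ValueError("no samples to bin")
    order = {s: i for i, s in enumerate(meta.sample_id)}
    missing = [s for s in attr.sample_ids if s not in order]
    if missing:
        raise KeyError(f"attributed samples absent from metadata: {missing[:5]}")
    ages = np.array([meta.age[order[s]] for s in attr.sample_ids])
    assignment = scheme.assign(ages)

    labels, intervals = scheme.labels(), scheme.intervals()
    kept_labels, kept_intervals, signed, magnitude, counts = [], [], [], [], []
    for i, (label, interval) in enumerate(zip(labels, intervals)):
        rows = np.flatnonzero(assignment == i)
        if rows.size == 0:
            logger.info("age bin %s is empty; dropped", label)
            continue
        kept_labels.append(label)
        kept_intervals.append(interval)
        signed.append(attr.values[rows].mean(axis=0))
        magnitude.append(np.abs(attr.values[rows]).mean(axis=0))
        counts.append(rows.size)
    return AgeBinProfile(
        bin_labels=kept_labels,
        bin_intervals=kept_intervals,
        feature_names=list(attr.feature_names),
        signed_mean=np.array(signed),
        magnitude_mean=np.array(magnitude),
        counts=np.array(counts),
    )


def select_extreme_cpgs(mean_magnitude: pd.Series, k: int) -> tuple[list[str], list[str]]:
    """Top-k and bottom-k features by mean attribution magnitude.

    Ties are broken by feature ID; with k >= the number of features both
    lists contain every feature.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    frame = mean_magnitude.rename("value").rename_axis("cpg").reset_index()
    top = frame.sort_values(["value", "cpg"], ascending=[False, True], kind="mergesort")
    bottom = frame.sort_values(["value", "cpg"], ascending=[True, True], kind="mergesort")
    return list(top["cpg"].head(k)), list(bottom["cpg"].head(k))
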