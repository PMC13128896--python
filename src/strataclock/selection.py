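"""Age- and sex-stratified Spearman feature selection.

Samples are grouped into age bins (half-open [lo, hi), last bin closed),
optionally split by sex, and each CpG is ranked within every stratum by the
absolute Spearman correlation of its betas with chronological age. The top
fraction of each stratum is retained and the per-stratum winners are merged
into a non-redundant feature set with selection provenance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, SampleMeta, SEX_FEMALE, SEX_MALE, SEX_UNKNOWN

__all__ = [
    "StratumScheme",
    "CorrelationTable",
    "FeatureSet",
    "assign_strata",
    "spearman_age_correlation",
    "pearson_age_correlation",
    "top_fraction_count",
    "stratum_correlations",
    "select_features",
    "classify_detectability",
]

DEFAULT_AGE_EDGES = (10.0, 40.0, 50.0, 70.0, 100.0)
_SEX_TAG = {SEX_FEMALE: "F", SEX_MALE: "M"}


@dataclass(frozen=True)
class StratumScheme:
    """Age-bin edges plus an optional within-bin sex split.

    Bins are half-open ``[lo, hi)``; the last bin is closed at its upper edge.
    """

    age_edges: tuple[float, ...] = DEFAULT_AGE_EDGES
    by_sex: bool = True

    def __post_init__(self) -> None:
        edges = tuple(self.age_edges)
        if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("age_edges must be strictly increasing with >= 2 entries")
        object.__setattr__(self, "age_edges", edges)

    @property
    def n_bins(self) -> int:
        return len(self.age_edges) - 1

    def bin_label(self, i: int) -> str:
        lo, hi = self.age_edges[i], self.age_edges[i + 1]
        return f"{lo:g}-{hi:g}"

    def bin_index(self, age: float) -> int:
        edges = self.age_edges
        if age < edges[0] or age > edges[-1]:
            raise ValueError(f"age {age} outside [{edges[0]}, {edges[-1]}]")
        if age == edges[-1]:  # last bin is closed
            return self.n_bins - 1
        return int(np.searchsorted(edges, age, side="right")) - 1

    def stratum_labels(self) -> list[str]:
        bins = [self.bin_label(i) for i in range(self.n_bins)]
        if not self.by_sex:
            return bins
        return [f"{b}/{s}" for b in bins for s in ("F", "M")]


@dataclass
class CorrelationTable:
    """Long-format per-stratum correlation results.

    One row per (cpg, stratum) with columns ``cpg, stratum, rho, n, p`` and
    optional ``pearson_r, pearson_p``. Undefined correlations (constant CpG
    or constant age) are NaN.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cpg", "stratum", "rho", "n", "p"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"correlation table missing columns: {sorted(missing)}")

    def strata(self) -> list[str]:
        return list(dict.fromkeys(self.frame["stratum"]))

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(Path(path), sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "CorrelationTable":
        return cls(pd.read_csv(Path(path), sep="\t"))


@dataclass
class FeatureSet:
    """Ordered, unique CpG IDs with per-stratum selection provenance."""

    cpgs: list[str]
    provenance: dict[str, set[str]]
    abs_rho: dict[str, float]  # max |rho| among the strata that selected it

    def __post_init__(self) -> None:
        if len(set(self.cpgs)) != len(self.cpgs):
            raise ValueError("feature set contains duplicate CpGs")
        empty = [c for c in self.cpgs if not self.provenance.get(c)]
        if empty:
            raise ValueError(f"features with empty provenance: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.cpgs)

    def __contains__(self, cpg: str) -> bool:
        return cpg in self.provenance

    def write(self, path: str | Path, provenance_path: str | Path | None = None) -> None:
        Path(path).write_text("\n".join(self.cpgs) + "\n")
        if provenance_path is not None:
            rows = [
                {"cpg": c, "strata": ";".join(sorted(self.provenance[c])), "abs_rho": self.abs_rho[c]}
                for c in self.cpgs
            ]
            pd.DataFrame(rows).to_csv(Path(provenance_path), sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "FeatureSet":
        cpgs = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
        return cls(cpgs, {c: {"file"} for c in cpgs}, {c: float("nan") for c in cpgs})


def assign_strata(meta: SampleMeta, scheme: StratumScheme) -> list[str]:
    """Assign each sample to exactly one (age-bin, sex) stratum label."""
    edges = scheme.age_edges
    out_of_range = [
        sid for sid, a in zip(meta.sample_id, meta.age) if a < edges[0] or a > edges[-1]
    ]
    if out_of_range:
        raise ValueError(
            f"ages outside [{edges[0]}, {edges[-1]}] for samples: {out_of_range[:5]}"
        )
    if scheme.by_sex:
        unknown = [sid for sid, s in zip(meta.sample_id, meta.sex) if s == SEX_UNKNOWN]
        if unknown:
            raise ValueError(f"unknown sex with sex stratification on: {unknown[:5]}")
    labels = []
    for age, sex in zip(meta.age, meta.sex):
        lab = scheme.bin_label(scheme.bin_index(age))
        if scheme.by_sex:
            lab = f"{lab}/{_SEX_TAG[int(sex)]}"
        labels.append(lab)
    return labels


def _rowwise_pearson(values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each row of ``values`` against ``y``, with t-test p-values.

    Rows with zero variance (or constant ``y``) get NaN.
    """
    n = y.size
    x = values - values.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((x**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ yc) / (sx * sy)
    r = np.where((sx == 0) | (sy == 0), np.nan, r)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, np.where(np.abs(r) == 1.0, 0.0, p))
    return r, p


def spearman_age_correlation(
    m: BetaMatrix | np.ndarray, ages: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-CpG Spearman rho (and p) between betas and age.

    Computed as Pearson on average ranks; requires n >= 3. Constant rows are
    reported NaN.
    """
    values = m.values if isinstance(m, BetaMatrix) else np.asarray(m, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if ages.size < 3:
        raise ValueError("Spearman correlation requires n >= 3")
    ranks = stats.rankdata(values, axis=1)
    age_ranks = stats.rankdata(ages)
    return _rowwise_pearson(ranks, age_ranks)


def pearson_age_correlation(
    m: BetaMatrix | np.ndarray, ages: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-CpG Pearson r (and p) between betas and age."""
    values = m.values if isinstance(m, BetaMatrix) else np.asarray(m, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    ages = np.asarray(ages, dtype=float)
    if ages.size < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    return _rowwise_pearson(values, ages)


def top_fraction_count(n_features: int, fraction: float) -> int:
    """Number of features kept per stratum: floor(fraction * n), min 1."""
    if n_features <= 0:
        raise ValueError("n_features must be positive")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return max(1, math.floor(fraction * n_features))


def stratum_correlations(
    m: BetaMatrix,
    meta: SampleMeta,
    scheme: StratumScheme | None = None,
    min_samples: int = 3,
    with_pearson: bool = False,
) -> CorrelationTable:
    """Spearman correlation of every CpG with age, within every stratum."""
    scheme = scheme or StratumScheme()
    labels = np.array(assign_strata(meta, scheme))
    frames = []
    for stratum in scheme.stratum_labels():
        idx = np.flatnonzero(labels == stratum)
        if idx.size < min_samples:
            continue
        rho, p = spearman_age_correlation(m.values[:, idx], meta.age[idx])
        frame = pd.DataFrame(
            {"cpg": m.probe_ids, "stratum": stratum, "rho": rho, "n": idx.size, "p": p}
        )
        if with_pearson:
            r, rp = pearson_age_correlation(m.values[:, idx], meta.age[idx])
            frame["pearson_r"] = r
            frame["pearson_p"] = rp
        frames.append(frame)
    if not frames:
        raise ValueError("no stratum has enough samples for correlation")
    return CorrelationTable(pd.concat(frames, ignore_index=True))


def select_features(
    table: CorrelationTable,
    fraction: float = 0.01,
    platform_probes: Sequence[str] | None = None,
) -> FeatureSet:
    """Union of per-stratum top-K CpGs by |rho|, with provenance.

    K = floor(fraction * F) per stratum, where F counts the CpGs with a
    defined rho in that stratum. Ties are broken by probe ID (lexicographic).
    An optional platform probe list is intersected at the end.
    """
    if fraction <= 0:
        raise ValueError("fraction must be positive; an empty selection is not allowed")
    provenance: dict[str, set[str]] = {}
    abs_rho: dict[str, float] = {}
    for stratum, group in table.frame.groupby("stratum", sort=False):
        usable = group.dropna(subset=["rho"])
        if usable.empty:
            continue
        k = top_fraction_count(len(usable), fraction)
        ranked = usable.assign(_a=usable["rho"].abs()).sort_values(
            ["_a", "cpg"], ascending=[False, True], kind="mergesort"
        )
        for _, row in ranked.head(k).iterrows():
            cpg = str(row["cpg"])
            provenance.setdefault(cpg, set()).add(str(stratum))
            abs_rho[cpg] = max(abs_rho.get(cpg, 0.0), abs(float(row["rho"])))
    if platform_probes is not None:
        keep = set(platform_probes)
        provenance = {c: s for c, s in provenance.items() if c in keep}
        abs_rho = {c: v for c, v in abs_rho.items() if c in keep}
    cpgs = sorted(provenance)
    return FeatureSet(cpgs, provenance, abs_rho)


def classify_detectability(
    m: BetaMatrix,
    meta: SampleMeta,
    scheme: StratumScheme | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify each CpG by stratified-Spearman vs pooled-Pearson detectability.

    Classes: ``both``, ``stratified_spearman_only``, ``pooled_pearson_only``,
    ``neither``. CpGs undefined under either test are labelled ``degenerate``
    with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    scheme = scheme or StratumScheme()
    labels = np.array(assign_strata(meta, scheme))
    strat_p = np.full(m.n_probes, np.nan)
    for stratum in np.unique(labels):
        idx = np.flatnonzero(labels == stratum)
        if idx.size < 3:
            continue
        _, p = spearman_age_correlation(m.values[:, idx], meta.age[idx])
        strat_p = np.fmin(strat_p, p)
    _, pooled_p = pearson_age_correlation(m, meta.age)

    classes = []
    degenerate = 0
    for sp, pp in zip(strat_p, pooled_p):
        if np.isnan(sp) or np.isnan(pp):
            classes.append("degenerate")
            degenerate += 1
            continue
        s_hit, p_hit = sp < alpha, pp < alpha
        if s_hit and p_hit:
            classes.append("both")
        elif s_hit:
            classes.append("stratified_spearman_only")
        elif p_hit:
            classes.append("pooled_pearson_only")
        else:
            classes.append("neither")
    if degenerate:
        warnings.warn(f"{degenerate} degenerate CpGs excluded from detectability classes")
    return pd.DataFrame(
        {
            "cpg": m.probe_ids,
            "class": classes,
            "min_stratified_spearman_p": strat_p,
            "pooled_pearson_p": pooled_p,
        }
    )
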