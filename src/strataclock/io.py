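"""Reading, writing and harmonizing methylation beta matrices and sample sheets.

Beta matrices are stored as delimited text with probes as rows by default
(series-matrix style); a flag handles transposed (samples-as-rows) input.
Missing values are encoded as empty fields or ``NA`` and held as NaN in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "SampleMeta",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_meta",
    "write_sample_meta",
    "collapse_epicv2",
    "harmonize",
    "impute_missing",
]

#: sex encoding used throughout the package
SEX_FEMALE = 0
SEX_MALE = 1
SEX_UNKNOWN = -1


@dataclass
class BetaMatrix:
    """Probes x samples methylation beta-values.

    Values are a float array of shape ``(n_probes, n_samples)``; missing
    entries are NaN. All non-missing values must lie in [0, 1].
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            dupes = _duplicates(self.probe_ids)
            raise ValueError(f"duplicate probe IDs: {sorted(dupes)[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValueError(f"duplicate sample IDs: {sorted(dupes)[:5]}")
        self._check_range()

    def _check_range(self) -> None:
        bad = np.where((self.values < 0) | (self.values > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValueError(
                f"beta value {self.values[i, j]} outside [0, 1] at probe "
                f"{self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(
            probe_ids=[str(p) for p in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def select_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        """Restrict to ``probes`` (in the given order)."""
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probes if p not in idx]
        if missing:
            raise KeyError(f"probes not in matrix: {missing[:5]}")
        rows = [idx[p] for p in probes]
        return BetaMatrix(list(probes), list(self.sample_ids), self.values[rows])


@dataclass
class SampleMeta:
    """Per-sample metadata: age (decimal years), sex (0=F, 1=M, -1=unknown), cohort."""

    sample_id: list[str]
    age: np.ndarray
    sex: np.ndarray
    cohort: list[str]

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=int)
        n = len(self.sample_id)
        if not (len(self.age) == len(self.sex) == len(self.cohort) == n):
            raise ValueError("sample metadata fields have unequal lengths")
        if len(set(self.sample_id)) != n:
            raise ValueError(f"duplicate sample IDs: {sorted(_duplicates(self.sample_id))[:5]}")
        if not np.all(np.isfinite(self.age)):
            raise ValueError("non-finite ages in sample metadata")
        bad = set(np.unique(self.sex)) - {SEX_FEMALE, SEX_MALE, SEX_UNKNOWN}
        if bad:
            raise ValueError(f"invalid sex codes {sorted(bad)}; expected 0, 1 or -1")

    def __len__(self) -> int:
        return len(self.sample_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "age": self.age,
                "sex": self.sex,
                "cohort": self.cohort,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleMeta":
        required = {"sample_id", "age", "sex", "cohort"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        return cls(
            sample_id=[str(s) for s in frame["sample_id"]],
            age=frame["age"].to_numpy(dtype=float),
            sex=frame["sex"].to_numpy(dtype=int),
            cohort=[str(c) for c in frame["cohort"]],
        )

    def subset(self, mask: np.ndarray) -> "SampleMeta":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SampleMeta(
            [self.sample_id[i] for i in idx],
            self.age[idx],
            self.sex[idx],
            [self.cohort[i] for i in idx],
        )


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_beta_matrix(path: str | Path, samples_as_rows: bool = False) -> BetaMatrix:
    """Read a delimited beta matrix (header row + ID column).

    Empty cells and ``NA`` are read as missing. With ``samples_as_rows`` the
    file is transposed after reading so the in-memory layout is always
    probes x samples.
    """
    path = Path(path)
    frame = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        na_values=["NA"],
        keep_default_na=False,
        dtype=str,
    )
    frame = frame.apply(pd.to_numeric, errors="raise")
    if samples_as_rows:
        frame = frame.T
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return BetaMatrix.from_frame(frame)


def write_beta_matrix(m: BetaMatrix, path: str | Path) -> None:
    path = Path(path)
    frame = m.to_frame()
    frame.index.name = "probe_id"
    frame.to_csv(path, sep=_sep_for(path), na_rep="NA")


def read_sample_meta(path: str | Path) -> SampleMeta:
    frame = pd.read_csv(Path(path))
    return SampleMeta.from_frame(frame)


def write_sample_meta(meta: SampleMeta, path: str | Path) -> None:
    meta.to_frame().to_csv(Path(path), index=False)


def canonical_probe_id(probe_id: str) -> str:
    """Strip the replicate suffix: text before the first underscore."""
    return probe_id.split("_", 1)[0]


def collapse_epicv2(m: BetaMatrix) -> BetaMatrix:
    """Collapse suffixed probe replicates to one beta per canonical CpG.

    Replicates (e.g. ``cg00000029_TC21``, ``cg00000029_BC21``) are averaged
    over their non-missing values; unsuffixed probes pass through unchanged.
    Output probe order follows first appearance of each canonical ID.
    """
    canon = [canonical_probe_id(p) for p in m.probe_ids]
    order: dict[str, int] = {}
    groups: dict[str, list[int]] = {}
    for i, c in enumerate(canon):
        if c not in groups:
            order[c] = len(order)
            groups[c] = []
        groups[c].append(i)
    out_ids = sorted(groups, key=order.__getitem__)
    out = np.empty((len(out_ids), m.n_samples))
    for k, c in enumerate(out_ids):
        rows = groups[c]
        if len(rows) == 1:
            out[k] = m.values[rows[0]]
        else:
            with np.errstate(invalid="ignore"):
                out[k] = np.nanmean(m.values[rows], axis=0)
    return BetaMatrix(out_ids, list(m.sample_ids), out)


def harmonize(matrices: Sequence[BetaMatrix]) -> tuple[list[BetaMatrix], list[str]]:
    """Restrict all matrices to their shared probes, rows in identical order.

    The shared list is ordered by the first matrix's probe order.
    """
    if len(matrices) < 2:
        raise ValueError("harmonize requires at least two matrices")
    shared = set(matrices[0].probe_ids)
    for m in matrices[1:]:
        shared &= set(m.probe_ids)
    if not shared:
        raise ValueError("no probes shared across all matrices")
    shared_ordered = [p for p in matrices[0].probe_ids if p in shared]
    return [m.select_probes(shared_ordered) for m in matrices], shared_ordered


def impute_missing(
    m: BetaMatrix,
    strategy: str = "probe_mean",
    reference_means: Mapping[str, float] | pd.Series | None = None,
) -> BetaMatrix:
    """Fill missing betas; observed entries are never altered.

    ``probe_mean`` fills each probe's NaNs with its own mean across samples.
    ``reference_then_probe_mean`` first fills from ``reference_means`` (probes
    with a reference entry take that value for all their NaNs), then falls
    back to probe means for the rest.
    """
    if strategy not in {"probe_mean", "reference_then_probe_mean"}:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    values = m.values.copy()
    missing = np.isnan(values)
    if strategy == "reference_then_probe_mean":
        if reference_means is None:
            raise ValueError("reference_then_probe_mean requires reference_means")
        ref = dict(reference_means.items()) if hasattr(reference_means, "items") else dict(reference_means)
        for i, probe in enumerate(m.probe_ids):
            if probe in ref and missing[i].any():
                values[i, missing[i]] = float(ref[probe])
        missing = np.isnan(values)
    # residual NAs: probe-wise means over the observed entries
    for i in np.flatnonzero(missing.any(axis=1)):
        observed = values[i, ~missing[i]]
        if observed.size == 0:
            raise ValueError(
                f"probe {m.probe_ids[i]!r} has no observed values and no reference mean"
            )
        values[i, missing[i]] = observed.mean()
    return BetaMatrix(list(m.probe_ids), list(m.sample_ids), values)
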