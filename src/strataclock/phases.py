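"""Hierarchical age-phase discovery with multiscale-bootstrap support.

Age-bin profiles (bins x features) are clustered with Ward.D2 linkage on
Euclidean distances. Cluster support follows the multiscale bootstrap: the
feature axis is resampled at several scales r, the fraction of reclusterings
that reproduce each observed edge gives BP_r, and the approximately unbiased
probability comes from the weighted fit

    psi_r = Phi^-1(1 - BP_r)  ~  v*sqrt(r) + c/sqrt(r),    AU = 1 - Phi(v - c).

Scales with degenerate BP_r (0 or 1) are excluded from the fit; if fewer
than two usable scales remain, AU falls back to BP with a flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import norm

from .attribution import AgeBinProfile, AgeBinScheme
from .io import BetaMatrix, SampleMeta

__all__ = [
    "Dendrogram",
    "EdgeSupport",
    "SupportedDendrogram",
    "PhaseAssignment",
    "DEFAULT_SCALES",
    "ward_cluster",
    "multiscale_bootstrap",
    "fit_au",
    "cut_phases",
    "compare_sex_phases",
    "bin_average_beta",
    "cluster_raw_beta",
]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 10))
DEFAULT_B = 1000
AU_SUPPORT_THRESHOLD = 0.95


@dataclass
class Dendrogram:
    """Ward.D2 merge tree over labelled objects (scipy linkage encoding)."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaf_labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def merge_members(self) -> list[frozenset[int]]:
        """Leaf-index member set of each internal node, in merge order."""
        n = self.n_leaves
        members: list[frozenset[int]] = []
        all_sets: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
        for a, b, _, _ in self.linkage:
            merged = all_sets[int(a)] | all_sets[int(b)]
            all_sets.append(merged)
            members.append(merged)
        return members


@dataclass
class EdgeSupport:
    """Bootstrap support of one internal edge of the observed dendrogram."""

    members: tuple[str, ...]
    height: float
    bp: float
    au: float
    v: float
    c: float
    bp_by_scale: dict[float, float]
    flag: str = ""  # "" | "degenerate_fit"


@dataclass
class SupportedDendrogram:
    """Dendrogram plus per-edge AU/BP support and bootstrap settings."""

    dendrogram: Dendrogram
    edges: list[EdgeSupport]
    scales: tuple[float, ...]
    n_bootstrap: int
    seed: int

    def edge_for(self, members: Sequence[str]) -> EdgeSupport | None:
        target = tuple(sorted(members))
        for e in self.edges:
            if tuple(sorted(e.members)) == target:
                return e
        return None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "leaf_labels": self.dendrogram.leaf_labels,
            "linkage": self.dendrogram.linkage.tolist(),
            "scales": list(self.scales),
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
            "edges": [
                {
                    "members": list(e.members),
                    "height": e.height,
                    "bp": e.bp,
                    "au": e.au,
                    "v": e.v,
                    "c": e.c,
                    "flag": e.flag,
                    "bp_by_scale": {str(k): v for k, v in e.bp_by_scale.items()},
                }
                for e in self.edges
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "SupportedDendrogram":
        payload = json.loads(Path(path).read_text())
        dendro = Dendrogram(np.array(payload["linkage"]), payload["leaf_labels"])
        edges = [
            EdgeSupport(
                members=tuple(e["members"]),
                height=e["height"],
                bp=e["bp"],
                au=e["au"],
                v=e["v"],
                c=e["c"],
                flag=e.get("flag", ""),
                bp_by_scale={float(k): v for k, v in e["bp_by_scale"].items()},
            )
            for e in payload["edges"]
        ]
        return cls(dendro, edges, tuple(payload["scales"]), payload["n_bootstrap"], payload["seed"])

    def to_newick(self) -> str:
        """Newick string with AU/BP annotations on internal nodes."""
        n = self.dendrogram.n_leaves
        Z = self.dendrogram.linkage
        members = self.dendrogram.merge_members()
        labels = self.dendrogram.leaf_labels
        heights = {i: 0.0 for i in range(n)}
        for k, (_, _, h, _) in enumerate(Z):
            heights[n + k] = h

        def render(node: int) -> str:
            if node < n:
                return labels[node].replace(" ", "_")
            k = node - n
            a, b = int(Z[k, 0]), int(Z[k, 1])
            blen_a = Z[k, 2] - heights[a]
            blen_b = Z[k, 2] - heights[b]
            edge = self.edge_for([labels[i] for i in members[k]])
            tag = f"au{edge.au:.3f}_bp{edge.bp:.3f}" if edge else ""
            return f"({render(a)}:{blen_a:.6g},{render(b)}:{blen_b:.6g}){tag}"

        return render(2 * n - 2) + ";"


def _as_matrix(profile: AgeBinProfile | pd.DataFrame | np.ndarray,
               labels: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
    if isinstance(profile, AgeBinProfile):
        return profile.signed_mean.astype(float), list(profile.bin_labels)
    if isinstance(profile, pd.DataFrame):
        return profile.to_numpy(dtype=float), [str(i) for i in profile.index]
    X = np.asarray(profile, dtype=float)
    labs = list(labels) if labels is not None else [f"bin{i}" for i in range(X.shape[0])]
    return X, labs


def ward_cluster(
    profile: AgeBinProfile | pd.DataFrame | np.ndarray,
    labels: Sequence[str] | None = None,
) -> Dendrogram:
    """Ward.D2 linkage (Euclidean) over the rows of a bins x features profile."""
    X, labs = _as_matrix(profile, labels)
    if X.shape[0] < 2:
        raise ValueError("clustering requires at least 2 bins")
    if np.isnan(X).any():
        raise ValueError("profile contains missing values")
    Z = hierarchy.linkage(X, method="ward")
    return Dendrogram(Z, labs)


def fit_au(
    scales: Sequence[float],
    bp_values: Sequence[float],
    n_bootstrap: int,
    weighted: bool = True,
) -> tuple[float, float, float, str]:
    """Fit the multiscale model and return (au, v, c, flag).

    BP is taken at (the scale closest to) r = 1. Scales with BP in {0, 1}
    are excluded from the fit; with fewer than two usable scales AU falls
    back to BP ("degenerate_fit").
    """
    scales = np.asarray(scales, dtype=float)
    bp_values = np.asarray(bp_values, dtype=float)
    bp_at_1 = float(bp_values[np.argmin(np.abs(scales - 1.0))])
    usable = (bp_values > 0) & (bp_values < 1)
    if usable.sum() < 2:
        return bp_at_1, float("nan"), float("nan"), "degenerate_fit"
    r = scales[usable]
    bp = bp_values[usable]
    psi = norm.ppf(1.0 - bp)
    design = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    if weighted:
        w = n_bootstrap * norm.pdf(psi) ** 2 / (bp * (1.0 - bp))
    else:
        w = np.ones_like(psi)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], psi * sw, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    au = float(1.0 - norm.cdf(v - c))
    return au, v, c, ""


def multiscale_bootstrap(
    profile: AgeBinProfile | pd.DataFrame | np.ndarray,
    labels: Sequence[str] | None = None,
    scales: Sequence[float] = DEFAULT_SCALES,
    n_bootstrap: int = DEFAULT_B,
    seed: int = 0,
    weighted: bool = True,
) -> SupportedDendrogram:
    """Attach AU/BP support to every edge of the Ward dendrogram.

    The resampling unit is the feature (column) axis: at scale r, columns are
    drawn with replacement to size round(r * F) and the rows reclustered; an
    edge's BP_r is the fraction of reclusterings containing its exact member
    set.
    """
    X, labs = _as_matrix(profile, labels)
    if n_bootstrap < 10:
        raise ValueError("n_bootstrap must be >= 10")
    scales = tuple(float(s) for s in scales)
    if not any(abs(s - 1.0) < 1e-9 for s in scales):
        scales = tuple(sorted({*scales, 1.0}))
    observed = ward_cluster(X, labs)
    members = observed.merge_members()
    member_keys = [frozenset(m) for m in members]

    n_features = X.shape[1]
    rng = np.random.default_rng(seed)
    counts = np.zeros((len(scales), len(member_keys)), dtype=int)
    for si, r in enumerate(scales):
        size = max(2, int(round(r * n_features)))
        for _ in range(n_bootstrap):
            cols = rng.integers(0, n_features, size=size)
            Zb = hierarchy.linkage(X[:, cols], method="ward")
            boot_sets = set()
            all_sets: list[frozenset[int]] = [frozenset([i]) for i in range(X.shape[0])]
            for a, b, _, _ in Zb:
                merged = all_sets[int(a)] | all_sets[int(b)]
                all_sets.append(merged)
                boot_sets.add(merged)
            for ei, key in enumerate(member_keys):
                if key in boot_sets:
                    counts[si, ei] += 1

    bp_matrix = counts / n_bootstrap
    edges: list[EdgeSupport] = []
    for ei, key in enumerate(member_keys):
        bp_by_scale = {s: float(bp_matrix[si, ei]) for si, s in enumerate(scales)}
        au, v, c, flag = fit_au(scales, bp_matrix[:, ei], n_bootstrap, weighted=weighted)
        bp = bp_by_scale[min(bp_by_scale, key=lambda s: abs(s - 1.0))]
        edges.append(
            EdgeSupport(
                members=tuple(labs[i] for i in sorted(key)),
                height=float(observed.linkage[ei, 2]),
                bp=bp,
                au=au,
                v=v,
                c=c,
                bp_by_scale=bp_by_scale,
                flag=flag,
            )
        )
    return SupportedDendrogram(observed, edges, scales, n_bootstrap, seed)


@dataclass
class PhaseAssignment:
    """Bin -> phase labels from cutting a dendrogram at a fixed height."""

    bin_labels: list[str]
    phases: list[int]
    cut_height: float
    phase_support: dict[int, float] = field(default_factory=dict)

    @property
    def n_phases(self) -> int:
        return len(set(self.phases))

    def supported_count(self, threshold: float = AU_SUPPORT_THRESHOLD) -> int:
        """Phases whose defining edge has AU >= threshold (singletons count)."""
        return sum(1 for au in self.phase_support.values() if au >= threshold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": self.bin_labels, "phase": self.phases, "cut_height": self.cut_height}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


def _phase_support(
    d: Dendrogram,
    edges: list[EdgeSupport] | None,
    flat: np.ndarray,
) -> dict[int, float]:
    support: dict[int, float] = {}
    lookup: dict[tuple[str, ...], float] = {}
    if edges is not None:
        lookup = {tuple(sorted(e.members)): e.au for e in edges}
    for phase in sorted(set(flat)):
        members = tuple(sorted(d.leaf_labels[i] for i in np.flatnonzero(flat == phase)))
        if len(members) == 1:
            support[int(phase)] = 1.0  # singleton: trivially its own cluster
        else:
            support[int(phase)] = lookup.get(members, float("nan"))
    return support


def cut_phases(
    d: SupportedDendrogram | Dendrogram,
    height: float | None = None,
    k: int | None = None,
) -> PhaseAssignment:
    """Cut the dendrogram into phases at a height, or at the minimal height
    yielding k clusters.

    Phases are renumbered 1.. in order of their first leaf.
    """
    if (height is None) == (k is None):
        raise ValueError("provide exactly one of height or k")
    dendro = d.dendrogram if isinstance(d, SupportedDendrogram) else d
    edges = d.edges if isinstance(d, SupportedDendrogram) else None
    n = dendro.n_leaves
    Z = dendro.linkage
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        cut_height = 0.0 if k == n else float(Z[n - k - 1, 2])
    else:
        if height < 0:
            raise ValueError("height must be >= 0")
        flat = hierarchy.fcluster(Z, t=height, criterion="distance")
        cut_height = float(height)
    # renumber phases by first-leaf order
    remap: dict[int, int] = {}
    phases = []
    for lab in flat:
        if lab not in remap:
            remap[lab] = len(remap) + 1
        phases.append(remap[lab])
    support = _phase_support(dendro, edges, np.asarray(flat))
    support = {remap[old]: au for old, au in support.items()}
    return PhaseAssignment(list(dendro.leaf_labels), phases, cut_height, support)


def compare_sex_phases(
    trees: Mapping[str, SupportedDendrogram],
    cut_height: float,
    threshold: float = AU_SUPPORT_THRESHOLD,
) -> dict[str, tuple[PhaseAssignment, int]]:
    """Apply one absolute cut height to every group's tree.

    Returns per group the phase assignment and the number of AU-supported
    phases. All trees must share an identical bin set.
    """
    bin_sets = {g: frozenset(t.dendrogram.leaf_labels) for g, t in trees.items()}
    if len(set(bin_sets.values())) > 1:
        raise ValueError(f"mismatched bin sets across groups: { {g: sorted(s)[:3] for g, s in bin_sets.items()} }")
    out = {}
    for group, tree in trees.items():
        assignment = cut_phases(tree, height=cut_height)
        out[group] = (assignment, assignment.supported_count(threshold))
    return out


def bin_average_beta(
    m: BetaMatrix,
    meta: SampleMeta,
    scheme: AgeBinScheme | None = None,
) -> pd.DataFrame:
    """Mean beta per age bin (bins x probes); empty bins dropped."""
    scheme = scheme or AgeBinScheme()
    order = {s: j for j, s in enumerate(m.sample_ids)}
    cols = np.array([order[s] for s in meta.sample_id])
    assignment = scheme.assign(meta.age)
    rows, labels = [], []
    for i, label in enumerate(scheme.labels()):
        sel = cols[assignment == i]
        if sel.size == 0:
            continue
        rows.append(np.nanmean(m.values[:, sel], axis=1))
        labels.append(label)
    if not rows:
        raise ValueError("no samples assignable to any age bin")
    return pd.DataFrame(np.array(rows), index=labels, columns=m.probe_ids)


def cluster_raw_beta(
    bin_beta: pd.DataFrame,
    scales: Sequence[float] = DEFAULT_SCALES,
    n_bootstrap: int = DEFAULT_B,
    seed: int = 0,
    weighted: bool = True,
) -> SupportedDendrogram:
    """Same clustering/bootstrap path as the attribution route, on raw betas."""
    return multiscale_bootstrap(
        bin_beta, scales=scales, n_bootstrap=n_bootstrap, seed=seed, weighted=weighted
    )
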