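"""Clock calibration metrics, clock ranking, delta-age and cell-composition
sensitivity analysis.

Conventions: R^2 is the squared Pearson correlation of predicted vs
chronological age; the slope/intercept come from least squares of predicted
on chronological; standard deviations use the n-1 denominator; delta-age is
predicted (biological) age minus chronological age.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationReport",
    "CellAdjustmentReport",
    "calibration_metrics",
    "rank_clocks",
    "delta_age",
    "cell_adjustment",
]


@dataclass
class CalibrationReport:
    """Calibration panel for one clock's predictions."""

    n: int
    mae: float
    medae: float
    rmse: float
    bias: float
    pearson_r: float
    spearman_rho: float
    r2: float
    slope: float
    intercept: float
    age_accel_sd: float

    def to_dict(self) -> dict:
        return asdict(self)

    def formatted(self, decimals: int = 3) -> dict:
        """Display rounding only; stored values keep full precision."""
        return {k: (round(v, decimals) if isinstance(v, float) else v) for k, v in asdict(self).items()}


def delta_age(predicted: np.ndarray, chronological: np.ndarray) -> np.ndarray:
    """Biological (predicted) age minus chronological age, elementwise."""
    predicted = np.asarray(predicted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    if predicted.shape != chronological.shape:
        raise ValueError("predicted and chronological vectors are not aligned")
    return predicted - chronological


def calibration_metrics(predicted: np.ndarray, chronological: np.ndarray) -> CalibrationReport:
    """Compute the full calibration panel.

    Requires n >= 3 finite pairs and non-constant chronological age (the
    regression of predicted on chronological is otherwise undefined).
    """
    predicted = np.asarray(predicted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    if predicted.shape != chronological.shape:
        raise ValueError("predicted and chronological vectors are not aligned")
    n = predicted.size
    if n < 3:
        raise ValueError("calibration requires n >= 3")
    if not (np.all(np.isfinite(predicted)) and np.all(np.isfinite(chronological))):
        raise ValueError("non-finite values in inputs")
    if np.ptp(chronological) == 0:
        raise ValueError("constant chronological age: slope undefined")

    err = delta_age(predicted, chronological)
    slope, intercept = np.polyfit(chronological, predicted, 1)
    if np.ptp(predicted) == 0:
        pearson = spearman = float("nan")
    else:
        pearson = float(stats.pearsonr(predicted, chronological)[0])
        spearman = float(stats.spearmanr(predicted, chronological)[0])
    return CalibrationReport(
        n=int(n),
        mae=float(np.mean(np.abs(err))),
        medae=float(np.median(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err**2))),
        bias=float(np.mean(err)),
        pearson_r=pearson,
        spearman_rho=spearman,
        r2=float(pearson**2),
        slope=float(slope),
        intercept=float(intercept),
        age_accel_sd=float(np.std(err, ddof=1)),
    )


def rank_clocks(reports: Mapping[str, CalibrationReport]) -> pd.DataFrame:
    """Rank clocks by ascending MAE (ties broken by clock name)."""
    if not reports:
        raise ValueError("at least one report required")
    rows = []
    for name, rep in reports.items():
        rows.append({"clock": name, **rep.to_dict()})
    frame = pd.DataFrame(rows).sort_values(["mae", "clock"], kind="mergesort").reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame


@dataclass
class CellAdjustmentReport:
    """Cell-composition sensitivity of one clock."""

    r2_cells: float  # variance of the clock explained by the fractions
    raw_r: float  # Pearson(clock, age)
    adjusted_r: float  # Pearson(residualized clock, age)
    delta_r: float  # adjusted - raw
    fraction_correlations: dict[str, float]
    degenerate_residuals: bool = False

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def cell_adjustment(
    clock: np.ndarray,
    fractions: pd.DataFrame,
    ages: np.ndarray,
) -> CellAdjustmentReport:
    """Regress a clock on cell fractions and compare raw vs adjusted age r.

    The clock (not age) is residualized on the fractions plus an intercept;
    rank-deficient fraction matrices are handled by the pseudo-inverse with a
    warning. Constant residuals yield adjusted r = 0 with a flag.
    """
    clock = np.asarray(clock, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(fractions) != clock.size or ages.size != clock.size:
        raise ValueError("clock, fractions and ages are not aligned")
    if fractions.isna().any().any() or not np.all(np.isfinite(clock)):
        raise ValueError("missing values in clock or fractions")
    F = fractions.to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(F)), F])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("rank-deficient fraction matrix; fitting via pseudo-inverse")
    coef, *_ = np.linalg.lstsq(design, clock, rcond=None)
    fitted = design @ coef
    residuals = clock - fitted
    ss_tot = np.sum((clock - clock.mean()) ** 2)
    r2_cells = float(1.0 - np.sum(residuals**2) / ss_tot) if ss_tot > 0 else 0.0
    r2_cells = float(np.clip(r2_cells, 0.0, 1.0))
    raw_r = float(stats.pearsonr(clock, ages)[0])
    degenerate = bool(np.ptp(residuals) < 1e-12)
    adjusted_r = 0.0 if degenerate else float(stats.pearsonr(residuals, ages)[0])
    frac_corr = {}
    for col in fractions.columns:
        x = fractions[col].to_numpy(dtype=float)
        frac_corr[str(col)] = float("nan") if np.ptp(x) == 0 else float(stats.pearsonr(clock, x)[0])
    return CellAdjustmentReport(
        r2_cells=r2_cells,
        raw_r=raw_r,
        adjusted_r=adjusted_r,
        delta_r=adjusted_r - raw_r,
        fraction_correlations=frac_corr,
        degenerate_residuals=degenerate,
    )
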