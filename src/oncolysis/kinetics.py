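"""Growth-kinetics summaries for live-cell-imaging well time series.

A screen produces, per well, a confluence-versus-time curve (and optionally a
dead-cell density curve).  The quantities used downstream are fold-change
curves normalized to the first scanned timepoint, their trapezoidal area under
the curve (AUC), and the treated/untreated AUC ratio.  A ratio of 1 means the
virus did not slow growth; smaller ratios mean stronger inhibition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("oncolysis.kinetics")

__all__ = [
    "WellSeries",
    "BaselineError",
    "normalize_to_baseline",
    "trapezoid_auc",
    "normalize_to_untreated",
    "death_index",
    "death_auc",
    "auc_table",
]


class BaselineError(ValueError):
    """The first scanned timepoint cannot anchor a fold-change curve."""


@dataclass
class WellSeries:
    """One well's time series for a cell line / MOI / replicate.

    ``moi`` is in PFU per cell, 0 meaning untreated.  ``repeat`` identifies
    the biological repeat and ``replicate`` the technical well within it.
    Confluence is percent of the image area covered; after baseline
    normalization the same slot holds the unitless fold change.
    """

    cell_line: str
    moi: float
    times: np.ndarray = field(repr=False)
    confluence: np.ndarray = field(repr=False)
    dead_per_mm2: Optional[np.ndarray] = field(default=None, repr=False)
    repeat: str = "r1"
    replicate: str = "w1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.confluence = np.asarray(self.confluence, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.confluence.shape:
            raise ValueError("times and confluence must be 1-D of equal length")
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.confluence)):
            raise ValueError("confluence contains non-finite values")
        if np.any(self.confluence < 0):
            raise ValueError("confluence must be non-negative")
        if self.dead_per_mm2 is not None:
            self.dead_per_mm2 = np.asarray(self.dead_per_mm2, dtype=float)
            if self.dead_per_mm2.shape != self.times.shape:
                raise ValueError("dead_per_mm2 length must match times")
            if np.any(self.dead_per_mm2 < 0) or not np.all(
                np.isfinite(self.dead_per_mm2)
            ):
                raise ValueError("dead_per_mm2 must be finite and non-negative")
        if float(self.moi) < 0:
            raise ValueError("moi must be non-negative")

    @property
    def untreated(self) -> bool:
        return float(self.moi) == 0.0


def normalize_to_baseline(series: WellSeries, mode: str = "divide") -> WellSeries:
    """Normalize each confluence value to the first timepoint.

    ``mode='divide'`` (default) yields fold change, so the first value is
    exactly 1 and the result is invariant to the instrument's absolute scale;
    ``mode='subtract'`` yields confluence gain, first value exactly 0.
    Dead-cell densities are left untouched.
    """
    baseline = float(series.confluence[0])
    if mode == "divide":
        if baseline <= 0:
            raise BaselineError(
                f"baseline confluence {baseline} <= 0 for {series.cell_line} "
                f"MOI {series.moi} {series.repeat}/{series.replicate}"
            )
        values = series.confluence / baseline
    elif mode == "subtract":
        values = series.confluence - baseline
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    return replace(series, confluence=values)


def trapezoid_auc(times: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal area under ``values`` on the observed time grid.

    Exact for piecewise-linear curves; no interpolation or extrapolation is
    performed beyond the grid.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("times and values must be 1-D of equal length")
    if t.size < 2:
        raise ValueError("AUC needs at least 2 points")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite input")
    return float(np.trapezoid(v, t))


def normalize_to_untreated(auc_treated: float, auc_untreated: float) -> float:
    """Treated/untreated AUC ratio; 1 means no growth inhibition."""
    if not np.isfinite(auc_untreated) or auc_untreated <= 0:
        raise ValueError(f"untreated AUC must be positive, got {auc_untreated}")
    return float(auc_treated) / float(auc_untreated)


def death_index(series: WellSeries) -> pd.DataFrame:
    """Dead cells per mm2 normalized pointwise to confluence.

    Timepoints with non-positive confluence are dropped with a warning; the
    AUC of the remaining index series is the well's cytotoxicity summary.
    """
    if series.dead_per_mm2 is None:
        raise ValueError("series has no dead-cell channel")
    keep = series.confluence > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.warning(
            "death_index: dropped %d timepoint(s) with confluence <= 0 for %s "
            "MOI %s %s/%s",
            dropped,
            series.cell_line,
            series.moi,
            series.repeat,
            series.replicate,
        )
    if not keep.any():
        raise ValueError("all timepoints dropped (confluence <= 0 throughout)")
    return pd.DataFrame(
        {
            "time_h": series.times[keep],
            "death_index": series.dead_per_mm2[keep] / series.confluence[keep],
        }
    )


def death_auc(series: WellSeries) -> float:
    """AUC of the confluence-normalized dead-cell index for one well."""
    idx = death_index(series)
    return trapezoid_auc(idx["time_h"].to_numpy(), idx["death_index"].to_numpy())


def auc_table(
    wells: Iterable[WellSeries], baseline_mode: str = "divide"
) -> pd.DataFrame:
    """Tidy per-condition AUC summary across a set of wells.

    For every (cell line, biological repeat, MOI): each technical well is
    baseline-normalized and integrated, the technical replicates are averaged
    (``auc_mean``), and the mean is divided by the same repeat's untreated
    mean (``auc_norm``).  Untreated rows therefore carry ``auc_norm == 1``
    exactly.  Columns: cell_line, repeat, moi, n, auc_mean, auc_norm.
    """
    rows = []
    for w in wells:
        normed = normalize_to_baseline(w, mode=baseline_mode)
        rows.append(
            {
                "cell_line": w.cell_line,
                "repeat": w.repeat,
                "moi": float(w.moi),
                "auc_raw": trapezoid_auc(normed.times, normed.confluence),
            }
        )
    if not rows:
        raise ValueError("no wells supplied")
    raw = pd.DataFrame(rows)
    summary = (
        raw.groupby(["cell_line", "repeat", "moi"], as_index=False)
        .agg(n=("auc_raw", "size"), auc_mean=("auc_raw", "mean"))
        .sort_values(["cell_line", "repeat", "moi"], kind="mergesort")
        .reset_index(drop=True)
    )

    def _norm(group: pd.DataFrame) -> pd.DataFrame:
        untreated = group.loc[group["moi"] == 0.0, "auc_mean"]
        if untreated.empty:
            raise ValueError(
                f"no untreated condition for {group.name}; cannot normalize"
            )
        ref = float(untreated.iloc[0])
        group = group.copy()
        group["auc_norm"] = [
            normalize_to_untreated(a, ref) for a in group["auc_mean"]
        ]
        return group

    out = (
        summary.groupby(["cell_line", "repeat"], group_keys=False)[summary.columns]
        .apply(_norm)
        .reset_index(drop=True)
    )
    return out
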