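"""Quantification of beta-lactamase surface-expression reporter assays.

The reporter enzyme is fused to the extracellular end of the subunit of
interest; in intact cells it cleaves the membrane-impermeant chromogen
nitrocefin only when the receptor reaches the plasma membrane, while lysed
wells report total expression.  The absorbance at 486 nm grows linearly with
time, so each well is summarized by the slope of an ordinary least-squares
regression over its linear range.  Surface-to-total ratios are background
subtracted:

    ratio = (mean surface slope - mean background slope)
          / (mean total slope - mean background slope)

and variant expression is reported as percent of the paired wild-type
experiment, aggregated geometrically across experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .profile_report import GroupStats, mean_ci95_log

__all__ = [
    "WellSeries",
    "PlateAssay",
    "SlopeResult",
    "SurfaceTotalResult",
    "od_slope",
    "surface_total_ratio",
    "percent_of_wt",
]

CONDITIONS = ("surface", "total", "background", "no_glun2_control")
REQUIRED_CONDITIONS = ("surface", "total", "background")


@dataclass
class WellSeries:
    """Absorbance time course of one well: minutes vs OD at 486 nm."""

    time_min: np.ndarray
    od486: np.ndarray
    well: str = ""
    condition: str = "surface"

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.od486 = np.asarray(self.od486, dtype=float)
        if self.time_min.shape != self.od486.shape or self.time_min.ndim != 1:
            raise ValueError("time and OD must be matching 1-D arrays")
        if self.time_min.size < 3:
            raise ValueError("a well needs at least 3 reads")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("read times must be strictly increasing")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown well condition {self.condition!r}")


@dataclass
class PlateAssay:
    """One experiment's wells for one construct."""

    wells: list[WellSeries]
    construct: str
    experiment_id: str

    def by_condition(self, condition: str) -> list[WellSeries]:
        return [w for w in self.wells if w.condition == condition]


@dataclass
class SlopeResult:
    slope: float  # OD/min
    r2: float
    n_reads_used: int
    truncated: bool = False


@dataclass
class SurfaceTotalResult:
    ratio: float
    ci95_low: float
    ci95_high: float
    experiment_id: str
    construct: str
    qc_no_glun2_ok: bool | None = None  # None when the control wells are absent
    warnings: list[str] = field(default_factory=list)


def od_slope(
    well: WellSeries,
    r2_threshold: float = 0.98,
    min_reads: int = 10,
    od_ceiling: float | None = None,
) -> SlopeResult:
    """OLS slope of OD vs time over the well's linear range.

    The fit window is the longest prefix whose regression R-squared meets
    ``r2_threshold`` (never shorter than ``min_reads`` reads, or the whole
    series if it has fewer) — nitrocefin turnover plateaus once substrate or
    enzyme saturates, and late reads would bias the slope down.  Reads above
    ``od_ceiling`` (detector saturation) are dropped first with the same
    truncation flag.
    """
    t = well.time_min
    y = well.od486
    truncated = False
    if od_ceiling is not None:
        keep = y <= od_ceiling
        if not keep.all():
            last = int(np.argmax(~keep))
            t, y = t[:last], y[:last]
            truncated = True
    if t.size < 3:
        raise ValueError("fewer than 3 usable reads in window")

    floor = min(min_reads, t.size)
    n = t.size
    while n > floor:
        res = stats.linregress(t[:n], y[:n])
        r2 = res.rvalue ** 2
        if r2 >= r2_threshold or math.isnan(r2):
            break
        n -= 1
        truncated = True
    res = stats.linregress(t[:n], y[:n])
    r2 = res.rvalue ** 2
    return SlopeResult(slope=float(res.slope), r2=float(0.0 if math.isnan(r2) else r2),
                       n_reads_used=int(n), truncated=truncated)


def surface_total_ratio(
    assay: PlateAssay,
    r2_threshold: float = 0.98,
    min_reads: int = 10,
    qc_fraction: float = 0.10,
) -> SurfaceTotalResult:
    """Background-subtracted surface/total slope ratio for one experiment.

    The no-GluN2 control, when present, is a QC check only (its surface
    signal must stay below ``qc_fraction`` of the cotransfected surface
    signal); it never enters the ratio.  The 95% CI is a delta-method
    approximation from the between-well scatter of the surface and total
    slopes.
    """
    for cond in REQUIRED_CONDITIONS:
        if not assay.by_condition(cond):
            raise ValueError(f"assay is missing required condition {cond!r}")

    def slopes(cond: str) -> np.ndarray:
        return np.array(
            [od_slope(w, r2_threshold, min_reads).slope for w in assay.by_condition(cond)]
        )

    s = slopes("surface")
    tt = slopes("total")
    b = slopes("background")
    num = float(s.mean() - b.mean())
    den = float(tt.mean() - b.mean())
    if den <= 0:
        raise ValueError("degenerate assay: total signal does not exceed background")
    ratio = num / den

    warnings: list[str] = []
    if num < 0:
        warnings.append("surface signal below background")

    # delta-method CI on a ratio of independent means
    def sem2(x: np.ndarray) -> float:
        return float(x.var(ddof=1) / x.size) if x.size > 1 else 0.0

    var = (ratio ** 2) * (
        (sem2(s) + sem2(b)) / num ** 2 + (sem2(tt) + sem2(b)) / den ** 2
    ) if num != 0 else 0.0
    half = 1.96 * math.sqrt(max(var, 0.0))

    qc_ok = None
    ctrl = assay.by_condition("no_glun2_control")
    if ctrl:
        ctrl_slope = float(np.mean([od_slope(w, r2_threshold, min_reads).slope for w in ctrl]))
        qc_ok = bool((ctrl_slope - b.mean()) < qc_fraction * max(num, 1e-300))
        if not qc_ok:
            warnings.append("no-GluN2 control surface signal exceeds QC threshold")

    return SurfaceTotalResult(
        ratio=ratio,
        ci95_low=ratio - half,
        ci95_high=ratio + half,
        experiment_id=assay.experiment_id,
        construct=assay.construct,
        qc_no_glun2_ok=qc_ok,
        warnings=warnings,
    )


def percent_of_wt(
    variant_ratios: Sequence[float | SurfaceTotalResult],
    wt_ratios: Sequence[float | SurfaceTotalResult],
) -> GroupStats:
    """Variant expression as percent of wild type, paired by experiment.

    Inputs are per-experiment surface/total ratios in matching experiment
    order; each pair yields 100 * variant / WT and pairs are aggregated as a
    geometric mean with 95% CI (ratio quantities are right-skewed).  WT
    normalizes to 100% by construction.
    """

    def val(x) -> float:
        return x.ratio if isinstance(x, SurfaceTotalResult) else float(x)

    v = [val(x) for x in variant_ratios]
    w = [val(x) for x in wt_ratios]
    if len(v) != len(w):
        raise ValueError("variant and WT experiments must be paired 1:1")
    if len(v) < 2:
        raise ValueError("percent_of_wt requires >= 2 paired experiments")
    if any(x <= 0 for x in w):
        raise ValueError("WT ratios must be positive")
    pct = [100.0 * a / b for a, b in zip(v, w)]
    return mean_ci95_log(pct, unit="% of WT")
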