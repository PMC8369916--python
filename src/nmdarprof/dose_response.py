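"""Concentration-response fitting for agonists and negative modulators.

Agonist activation follows the Hill equation

    Response(%) = 100 / (1 + (EC50 / [agonist])^N)

where EC50 is the concentration producing a half-maximal response and N is
the Hill slope.  Inhibition by a negative allosteric modulator (Mg2+, Zn2+)
follows the descending logistic with a residual plateau

    Response(%) = (100 - minimum) / (1 + ([modulator] / IC50)^N) + minimum

where ``minimum`` is the residual response at saturating modulator.

Fits are per cell (one oocyte / one patched cell), optimized in log10(EC50)
space with a bounded Hill slope and a multi-start initialization; per-cell
parameter estimates are then aggregated as mean with 95% CI across cells,
which is how composite curves are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import lmfit
import numpy as np
import pandas as pd

from .profile_report import GroupStats, mean_ci95

__all__ = [
    "ConcentrationSeries",
    "HillFit",
    "InhibitionFit",
    "CRCFitConfig",
    "hill_response",
    "inhibition_response",
    "fit_activation",
    "fit_inhibition",
    "composite_curve",
    "CompositeCurve",
]


@dataclass
class ConcentrationSeries:
    """One cell's responses across a concentration ladder.

    ``concentration`` is molar, strictly positive and ascending; ``response``
    is raw amplitude (nA) for agonist series or percent of the unmodulated
    control for inhibitor series.
    """

    cell_id: str
    construct: str
    compound: str
    role: str  # "agonist" | "inhibitor"
    concentration: np.ndarray
    response: np.ndarray
    co_agonist: str | None = None
    co_agonist_molar: float | None = None

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.role not in ("agonist", "inhibitor"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.concentration.ndim != 1 or self.concentration.shape != self.response.shape:
            raise ValueError("concentration and response must be matching 1-D arrays")
        if np.any(self.concentration <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentration) <= 0):
            raise ValueError("concentrations must be strictly ascending")

    @property
    def n_concentrations(self) -> int:
        return int(np.unique(self.concentration).size)


@dataclass
class HillFit:
    """Fitted activation parameters for one cell."""

    ec50: float
    hill: float
    top: float
    rss: float
    ci95_ec50: tuple[float, float] | None
    converged: bool
    cell_id: str = ""
    construct: str = ""
    compound: str = ""
    message: str = ""


@dataclass
class InhibitionFit:
    """Fitted inhibition parameters for one cell."""

    ic50: float
    hill: float
    minimum: float
    rss: float
    ci95_ic50: tuple[float, float] | None
    converged: bool
    cell_id: str = ""
    construct: str = ""
    compound: str = ""
    message: str = ""
    warning: str | None = None


@dataclass
class CRCFitConfig:
    """Fitting options shared by activation and inhibition fits.

    hill_bounds : allowed Hill-slope range; NMDAR agonist curves typically
        fit between ~1 and ~2, the default range is deliberately loose.
    n_starts : number of log-spaced EC50/IC50 initializations (multi-start
        guards against local minima on sparse ladders).
    normalize : "fitted_top" divides responses by the fitted maximum (robust
        when the top concentration is sub-saturating for shifted variants);
        "max_point" divides by the largest observed response.
    """

    hill_bounds: tuple[float, float] = (0.3, 5.0)
    n_starts: int = 5
    normalize: str = "fitted_top"
    min_points: int = 4


_BOUND_EPS = 1e-6


def hill_response(concentration, ec50: float, hill: float):
    """Fractional occupancy/response 1 / (1 + (EC50/c)^N), in (0, 1).

    Strictly increasing in concentration.  Accepts scalars or arrays.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c <= 0) or ec50 <= 0 or hill <= 0:
        raise ValueError("hill_response requires strictly positive arguments")
    out = 1.0 / (1.0 + (ec50 / c) ** hill)
    return float(out) if np.isscalar(concentration) else out


def inhibition_response(concentration, ic50: float, hill: float, minimum: float):
    """Percent response remaining under a negative modulator.

    (100 - minimum) / (1 + (c/IC50)^N) + minimum; equals 100 at c = 0 and
    decays to ``minimum`` at saturation.  Concentration zero is allowed.
    """
    c = np.asarray(concentration, dtype=float)
    if ic50 <= 0 or hill <= 0:
        raise ValueError("IC50 and Hill slope must be positive")
    if not 0.0 <= minimum < 100.0:
        raise ValueError("minimum must lie in [0, 100)")
    if np.any(c < 0):
        raise ValueError("modulator concentration must be non-negative")
    out = (100.0 - minimum) / (1.0 + (c / ic50) ** hill) + minimum
    return float(out) if np.isscalar(concentration) else out


def _at_bound(value: float, lo: float, hi: float) -> bool:
    span = hi - lo
    return value - lo < _BOUND_EPS * span or hi - value < _BOUND_EPS * span


def _ec50_ci(result: lmfit.minimizer.MinimizerResult, name: str) -> tuple[float, float] | None:
    par = result.params[name]
    if par.stderr is None or not np.isfinite(par.stderr):
        return None
    lo = par.value - 1.96 * par.stderr
    hi = par.value + 1.96 * par.stderr
    return (10.0 ** lo, 10.0 ** hi)


def fit_activation(series: ConcentrationSeries, config: CRCFitConfig | None = None) -> HillFit:
    """Least-squares Hill fit of an agonist activation series.

    The model is top / (1 + (EC50/c)^N) with EC50 optimized in log10 space,
    N bounded per config, and top free (responses need not be
    pre-normalized).  Non-convergence — optimizer failure, parameters pinned
    at bounds, or a flat/non-monotone series — is flagged rather than
    silently defaulted.
    """
    cfg = config or CRCFitConfig()
    if series.role != "agonist":
        raise ValueError("fit_activation requires role='agonist'")
    if series.n_concentrations < cfg.min_points:
        raise ValueError(
            f"activation fit requires >= {cfg.min_points} distinct concentrations, "
            f"got {series.n_concentrations}"
        )
    c = series.concentration
    y = series.response
    if np.any(y < 0):
        raise ValueError("agonist responses must be non-negative after baseline correction")

    log_lo = math.log10(c.min()) - 3.0
    log_hi = math.log10(c.max()) + 3.0
    top_guess = float(y.max()) if y.max() > 0 else 1.0

    def residual(params):
        ec50 = 10.0 ** params["log_ec50"].value
        return params["top"].value / (1.0 + (ec50 / c) ** params["hill"].value) - y

    best = None
    starts = np.linspace(math.log10(c.min()), math.log10(c.max()), cfg.n_starts)
    for s in starts:
        params = lmfit.Parameters()
        params.add("log_ec50", value=float(s), min=log_lo, max=log_hi)
        params.add("hill", value=1.5, min=cfg.hill_bounds[0], max=cfg.hill_bounds[1])
        params.add("top", value=top_guess, min=1e-12 * max(top_guess, 1.0),
                   max=50.0 * max(top_guess, 1.0))
        try:
            res = lmfit.minimize(residual, params, method="least_squares",
                                 ftol=1e-15, xtol=1e-15, gtol=1e-15)
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        rss = float(np.sum(res.residual ** 2))
        if best is None or rss < best[0]:
            best = (rss, res)

    if best is None:
        return HillFit(math.nan, math.nan, math.nan, math.inf, None, False,
                       series.cell_id, series.construct, series.compound,
                       "optimizer failed on all starts")
    rss, res = best
    p = res.params
    ec50 = 10.0 ** p["log_ec50"].value
    converged = bool(res.success)
    msg = ""
    if _at_bound(p["log_ec50"].value, log_lo, log_hi):
        converged, msg = False, "EC50 at bound"
    elif _at_bound(p["hill"].value, *cfg.hill_bounds):
        converged, msg = False, "Hill slope at bound"
    # Flat series: fitted dynamic range indistinguishable from constant.
    span = hill_response(c.max(), ec50, p["hill"].value) - hill_response(c.min(), ec50, p["hill"].value)
    if span * p["top"].value < 1e-9 * max(top_guess, 1.0):
        converged, msg = False, "flat series (no concentration dependence)"
    return HillFit(
        ec50=float(ec50),
        hill=float(p["hill"].value),
        top=float(p["top"].value),
        rss=rss,
        ci95_ec50=_ec50_ci(res, "log_ec50"),
        converged=converged,
        cell_id=series.cell_id,
        construct=series.construct,
        compound=series.compound,
        message=msg,
    )


def fit_inhibition(series: ConcentrationSeries, config: CRCFitConfig | None = None) -> InhibitionFit:
    """Least-squares fit of the inhibition-with-plateau model.

    Responses are percent of the unmodulated control (the zero-modulator
    response is 100% by construction and need not appear in the series).
    The residual ``minimum`` is constrained to [0, 100).  If no tested
    concentration exceeds the fitted IC50 the plateau is unconstrained by
    the data and a wide-CI warning is recorded in the result.
    """
    cfg = config or CRCFitConfig()
    if series.role != "inhibitor":
        raise ValueError("fit_inhibition requires role='inhibitor'")
    if series.n_concentrations < cfg.min_points:
        raise ValueError(
            f"inhibition fit requires >= {cfg.min_points} distinct concentrations, "
            f"got {series.n_concentrations}"
        )
    c = series.concentration
    y = series.response

    log_lo = math.log10(c.min()) - 3.0
    log_hi = math.log10(c.max()) + 3.0

    def residual(params):
        ic50 = 10.0 ** params["log_ic50"].value
        return (
            (100.0 - params["minimum"].value)
            / (1.0 + (c / ic50) ** params["hill"].value)
            + params["minimum"].value
            - y
        )

    best = None
    starts = np.linspace(math.log10(c.min()), math.log10(c.max()), cfg.n_starts)
    for s in starts:
        params = lmfit.Parameters()
        params.add("log_ic50", value=float(s), min=log_lo, max=log_hi)
        params.add("hill", value=1.0, min=cfg.hill_bounds[0], max=cfg.hill_bounds[1])
        params.add("minimum", value=float(max(0.0, min(y.min(), 99.0))), min=0.0,
                   max=100.0 - 1e-9)
        try:
            res = lmfit.minimize(residual, params, method="least_squares",
                                 ftol=1e-15, xtol=1e-15, gtol=1e-15)
        except Exception:  # pragma: no cover
            continue
        rss = float(np.sum(res.residual ** 2))
        if best is None or rss < best[0]:
            best = (rss, res)

    if best is None:
        return InhibitionFit(math.nan, math.nan, math.nan, math.inf, None, False,
                             series.cell_id, series.construct, series.compound,
                             "optimizer failed on all starts")
    rss, res = best
    p = res.params
    ic50 = 10.0 ** p["log_ic50"].value
    converged = bool(res.success)
    msg = ""
    if _at_bound(p["log_ic50"].value, log_lo, log_hi):
        converged, msg = False, "IC50 at bound"
    elif _at_bound(p["hill"].value, *cfg.hill_bounds):
        converged, msg = False, "Hill slope at bound"
    # Uninhibited series: model span indistinguishable from constant 100%.
    model_span = inhibition_response(c.min(), ic50, p["hill"].value, p["minimum"].value) \
        - inhibition_response(c.max(), ic50, p["hill"].value, p["minimum"].value)
    if model_span < 1e-6 and float(np.ptp(y)) < 1e-6:
        converged, msg = False, "no inhibition observed"
    warning = None
    if converged and c.max() < ic50:
        warning = "no concentrations above IC50; plateau poorly constrained"
    return InhibitionFit(
        ic50=float(ic50),
        hill=float(p["hill"].value),
        minimum=float(p["minimum"].value),
        rss=rss,
        ci95_ic50=_ec50_ci(res, "log_ic50"),
        converged=converged,
        cell_id=series.cell_id,
        construct=series.construct,
        compound=series.compound,
        message=msg,
        warning=warning,
    )


@dataclass
class CompositeCurve:
    """Pointwise-averaged normalized responses plus aggregate parameters."""

    table: pd.DataFrame  # concentration, mean, ci95_low, ci95_high, n
    ec50_stats: GroupStats  # mean of per-cell EC50/IC50 estimates
    hill_stats: GroupStats
    fits: list = field(default_factory=list)
    excluded: list = field(default_factory=list)  # (cell_id, reason)
    degenerate: bool = False  # single cell: pass-through, CI not estimable


def composite_curve(
    series_list: Sequence[ConcentrationSeries],
    grid: Iterable[float] | None = None,
    config: CRCFitConfig | None = None,
) -> CompositeCurve:
    """Aggregate one construct/compound's cells into a composite curve.

    Each cell is fitted individually; its responses are normalized to the
    fitted top (activation) or taken as-is in percent (inhibition), then
    averaged pointwise across cells with a 95% CI.  Aggregate EC50/IC50 and
    Hill slope are the mean of per-cell estimates with 95% CI — not a pooled
    global fit.  Cells whose fits did not converge are excluded with a
    recorded reason.
    """
    if not series_list:
        raise ValueError("composite_curve requires at least one series")
    constructs = {s.construct for s in series_list}
    compounds = {s.compound for s in series_list}
    roles = {s.role for s in series_list}
    if len(constructs) > 1 or len(compounds) > 1 or len(roles) > 1:
        raise ValueError(
            f"mixed grouping: constructs={constructs}, compounds={compounds}, roles={roles}"
        )
    role = series_list[0].role

    fits = []
    excluded = []
    normalized = {}
    for s in series_list:
        fit = fit_activation(s, config) if role == "agonist" else fit_inhibition(s, config)
        if not fit.converged:
            excluded.append((s.cell_id, fit.message or "non-converged"))
            continue
        fits.append(fit)
        if role == "agonist":
            normalized[s.cell_id] = (s.concentration, 100.0 * s.response / fit.top)
        else:
            normalized[s.cell_id] = (s.concentration, s.response)

    if not fits:
        raise ValueError("no cell fit converged; cannot build composite curve")

    if grid is None:
        grid_arr = np.unique(np.concatenate([c for c, _ in normalized.values()]))
    else:
        grid_arr = np.asarray(sorted(grid), dtype=float)

    rows = []
    for conc in grid_arr:
        vals = [
            float(resp[np.isclose(c, conc)][0])
            for c, resp in normalized.values()
            if np.any(np.isclose(c, conc))
        ]
        if not vals:
            continue
        gs = mean_ci95(vals, unit="%")
        rows.append({"concentration": conc, "mean": gs.mean, "ci95_low": gs.ci95_low,
                     "ci95_high": gs.ci95_high, "n": gs.n})
    table = pd.DataFrame(rows)

    x50 = [f.ec50 if role == "agonist" else f.ic50 for f in fits]
    hills = [f.hill for f in fits]
    unit = "M"
    return CompositeCurve(
        table=table,
        ec50_stats=mean_ci95(x50, unit=unit),
        hill_stats=mean_ci95(hills, unit=""),
        fits=fits,
        excluded=excluded,
        degenerate=len(fits) < 2,
    )
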