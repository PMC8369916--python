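"""Composite relative synaptic and nonsynaptic charge-transfer indices.

A loss-of-function missense variant can alter several receptor properties at
once — deactivation time course, open probability, surface expression,
agonist potency, Mg2+ block.  The composite index multiplies the
mutant-to-wild-type ratio of each component to estimate the net change in
charge transferred per synaptic event (or per unit time at ambient,
nonsynaptic agonist levels):

    synaptic    = (tau_w ratio) * (P ratio) * (Surf ratio)
                  * R_GLY * R_GLU(synaptic) * (Mg ratio)
    nonsynaptic =               (P ratio) * (Surf ratio)
                  * R_GLY * R_GLU(nonsynaptic) * (Mg ratio)

R_X is the mutant/WT ratio of fractional receptor occupancy
1 / (1 + (EC50/[X])^N) at a fixed concentration: glycine 3 uM, glutamate
1 mM for the synaptic case and 0.1 uM (ambient) for the nonsynaptic case.
The deactivation term drops from the nonsynaptic index because tonic
activation has no decaying transient.  Wild type against itself gives
exactly 1 for every composition.

Hill slopes are often not estimable from sparse ladders; a configurable
default (1.5 for both agonists, typical of NMDAR composite fits) is used
when a fitted slope is unavailable, and :func:`sensitivity_scan` quantifies
how strongly the indices depend on that assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .dose_response import HillFit, hill_response, inhibition_response

__all__ = [
    "ComponentRatios",
    "ChargeTransferResult",
    "DEFAULT_HILL_GLU",
    "DEFAULT_HILL_GLY",
    "SYNAPTIC_GLU_M",
    "NONSYNAPTIC_GLU_M",
    "GLYCINE_M",
    "relative_occupancy",
    "mg_ratio_from_ic50",
    "synaptic_index",
    "nonsynaptic_index",
    "sensitivity_scan",
]

# Fixed evaluation concentrations for the occupancy terms (molar).
SYNAPTIC_GLU_M = 1e-3
NONSYNAPTIC_GLU_M = 1e-7
GLYCINE_M = 3e-6

DEFAULT_HILL_GLU = 1.5
DEFAULT_HILL_GLY = 1.5


@dataclass
class ComponentRatios:
    """Mutant/WT ratios entering the composite indices.

    Every ratio must be positive; ``provenance`` records which fit or assay
    produced each term so the composite is auditable.
    """

    tau_w_ratio: float | None = None
    p_ratio: float | None = None
    surf_ratio: float | None = None
    mg_ratio: float | None = None
    r_gly: float | None = None
    r_glu_synaptic: float | None = None
    r_glu_nonsynaptic: float | None = None
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("tau_w_ratio", "p_ratio", "surf_ratio", "mg_ratio",
                     "r_gly", "r_glu_synaptic", "r_glu_nonsynaptic"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass
class ChargeTransferResult:
    """One composite index with its full multiplicative decomposition."""

    index: float
    fold_reduction: float
    kind: str  # "synaptic" | "nonsynaptic"
    composition: dict[str, float]
    hill_assumptions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prod = math.prod(self.composition.values())
        if not math.isclose(prod, self.index, rel_tol=1e-12):
            raise ValueError("index must equal the product of its composition terms")


def _hill_of(fit: HillFit | tuple[float, float] | float, default_hill: float | None):
    """Extract (ec50, hill) from a HillFit, an (ec50, hill) pair, or a bare EC50."""
    if isinstance(fit, HillFit):
        if not fit.converged:
            raise ValueError("occupancy requires a converged fit")
        return fit.ec50, fit.hill
    if isinstance(fit, tuple):
        return float(fit[0]), float(fit[1])
    if default_hill is None:
        raise ValueError("bare EC50 supplied but no default Hill slope configured")
    return float(fit), float(default_hill)


def relative_occupancy(
    mut_fit: HillFit | tuple[float, float] | float,
    wt_fit: HillFit | tuple[float, float] | float,
    concentration: float,
    default_hill: float | None = None,
) -> float:
    """Mutant/WT occupancy ratio at a fixed agonist concentration.

    Each argument is a :class:`HillFit`, an ``(ec50, hill)`` pair, or a bare
    EC50 (molar) combined with ``default_hill``.  In the low-concentration
    limit the ratio approaches (EC50_wt / EC50_mut)^N.
    """
    ec50_m, hill_m = _hill_of(mut_fit, default_hill)
    ec50_w, hill_w = _hill_of(wt_fit, default_hill)
    return hill_response(concentration, ec50_m, hill_m) / hill_response(
        concentration, ec50_w, hill_w
    )


def mg_ratio_from_ic50(
    ic50_mut: float,
    ic50_wt: float,
    concentration: float = 1e-3,
    hill: float = 1.0,
    minimum: float = 0.0,
    mode: str = "fraction_remaining",
) -> float:
    """Mutant/WT Mg2+ term at a fixed blocker concentration (default 1 mM).

    ``fraction_remaining`` (default) takes the ratio of unblocked fractional
    responses from the inhibition model — charge scales with the current that
    flows, i.e. with what Mg2+ leaves unblocked.  ``percent_inhibition``
    instead takes the ratio of the blocked percentages.  Concentrations and
    IC50s share units (molar here).
    """
    conc = concentration
    rem_mut = inhibition_response(conc, ic50_mut, hill, minimum)
    rem_wt = inhibition_response(conc, ic50_wt, hill, minimum)
    if mode == "fraction_remaining":
        return rem_mut / rem_wt
    if mode == "percent_inhibition":
        return (100.0 - rem_mut) / (100.0 - rem_wt)
    raise ValueError(f"unknown Mg mode {mode!r}")


def _require(ratios: ComponentRatios, names: Sequence[str]) -> dict[str, float]:
    comp = {}
    for n in names:
        v = getattr(ratios, n)
        if v is None:
            raise ValueError(f"missing component ratio {n!r}")
        comp[n] = float(v)
    return comp


def synaptic_index(
    ratios: ComponentRatios,
    include_p_ratio: bool = True,
    hill_assumptions: dict[str, float] | None = None,
) -> ChargeTransferResult:
    """Composite synaptic charge-transfer index.

    ``include_p_ratio`` toggles the open-probability term.  The full
    composition includes it; the alternative composition without it is also
    a first-class output because published composite values computed from
    component tables are often reproducible only with one of the two, and
    the choice must stay explicit rather than silently reconciled.
    """
    names = ["tau_w_ratio", "surf_ratio", "r_gly", "r_glu_synaptic", "mg_ratio"]
    if include_p_ratio:
        names.insert(1, "p_ratio")
    comp = _require(ratios, names)
    index = math.prod(comp.values())
    return ChargeTransferResult(
        index=index,
        fold_reduction=1.0 / index,
        kind="synaptic",
        composition=comp,
        hill_assumptions=dict(hill_assumptions or {}),
    )


def nonsynaptic_index(
    ratios: ComponentRatios,
    hill_assumptions: dict[str, float] | None = None,
) -> ChargeTransferResult:
    """Composite nonsynaptic (tonic) charge-transfer index.

    Five terms: P, Surf, R_GLY, R_GLU at ambient glutamate, Mg.  The
    deactivation term is excluded by construction.
    """
    comp = _require(
        ratios, ["p_ratio", "surf_ratio", "r_gly", "r_glu_nonsynaptic", "mg_ratio"]
    )
    index = math.prod(comp.values())
    return ChargeTransferResult(
        index=index,
        fold_reduction=1.0 / index,
        kind="nonsynaptic",
        composition=comp,
        hill_assumptions=dict(hill_assumptions or {}),
    )


def sensitivity_scan(
    ec50_glu_mut: float,
    ec50_glu_wt: float,
    ec50_gly_mut: float,
    ec50_gly_wt: float,
    base_ratios: ComponentRatios,
    hill_grid: Iterable[float],
    hill_gly: float = DEFAULT_HILL_GLY,
    include_p_ratio: bool = True,
) -> pd.DataFrame:
    """Recompute both indices across assumed glutamate Hill slopes.

    The occupancy terms are rebuilt at each grid point from the EC50 pairs
    (molar); tau/P/Surf/Mg ratios are taken from ``base_ratios`` unchanged.
    When EC50_mut > EC50_wt the indices are monotone decreasing in the
    glutamate Hill slope, so the grid brackets the unprinted-slope
    uncertainty.
    """
    grid = list(hill_grid)
    if not grid:
        raise ValueError("hill_grid must be non-empty")
    rows = []
    for n_glu in grid:
        r = ComponentRatios(
            tau_w_ratio=base_ratios.tau_w_ratio,
            p_ratio=base_ratios.p_ratio,
            surf_ratio=base_ratios.surf_ratio,
            mg_ratio=base_ratios.mg_ratio,
            r_gly=relative_occupancy(
                (ec50_gly_mut, hill_gly), (ec50_gly_wt, hill_gly), GLYCINE_M
            ),
            r_glu_synaptic=relative_occupancy(
                (ec50_glu_mut, n_glu), (ec50_glu_wt, n_glu), SYNAPTIC_GLU_M
            ),
            r_glu_nonsynaptic=relative_occupancy(
                (ec50_glu_mut, n_glu), (ec50_glu_wt, n_glu), NONSYNAPTIC_GLU_M
            ),
        )
        hills = {"glutamate": float(n_glu), "glycine": float(hill_gly)}
        rows.append({
            "hill_glu": float(n_glu),
            "synaptic_index": synaptic_index(r, include_p_ratio, hills).index,
            "nonsynaptic_index": nonsynaptic_index(r, hills).index,
        })
    return pd.DataFrame(rows)
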