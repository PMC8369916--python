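"""Synthetic electrophysiology and plate-reader data with known ground truth.

Every analysis stage in this package consumes one of four data classes:
concentration-response amplitude tables, sampled current traces,
plate-reader absorbance time courses, and before/after amplitude pairs.
The generators here emulate each of them directly from the model the
corresponding analysis fits — Hill or inhibition curves with multiplicative
amplitude noise across replicate cells, bi-exponential current decays with
additive sample noise at 20 kHz, linear nitrocefin absorbance ramps with
per-well scatter, and lognormally scattered potentiation pairs — so that
downstream fits can be tested against exact generating parameters without
any real recordings.

Noise model choices: amplitudes get multiplicative Gaussian noise
(CV-parameterized, truncated at zero) so they stay non-negative; trace
samples get additive Gaussian noise (injected post-filter — hardware
filtering is not modeled); ratios get mean-unbiased lognormal scatter so
they stay positive.  Randomness derives from a single seed with a separate
child stream per generator and per cell, so adding cells to a request never
perturbs the cells generated before them.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field

from .dose_response import ConcentrationSeries, hill_response, inhibition_response
from .kinetics import ApplicationProtocol, CurrentTrace
from .open_probability import PotentiationPair
from .surface_expression import PlateAssay, WellSeries

__all__ = [
    "SimulationConfig",
    "gen_crc_series",
    "gen_inhibition_series",
    "gen_decay_trace",
    "gen_betalac_plate",
    "gen_potentiation_pairs",
    "half_log_ladder",
]

# Per-generator stream tags: keep streams independent across generators
# sharing one seed.
_STREAM_CRC = 1
_STREAM_INHIB = 2
_STREAM_TRACE = 3
_STREAM_PLATE = 4
_STREAM_PAIRS = 5


class SimulationConfig(BaseModel):
    """Shared simulation settings.

    seed : master seed; identical configs produce bit-identical outputs.
    n_cells : replicate cells per concentration-response request.
    noise_cv : coefficient of variation of multiplicative amplitude noise
        (also the per-well rate CV for plate assays and the lognormal sigma
        for potentiation pairs).
    trace_noise_sd : additive current noise per sample, pA.
    sampling_rate : trace sampling rate, kHz.
    plate_noise_sd : additive absorbance noise per read, OD units.
    """

    seed: int = 0
    n_cells: int = Field(default=10, ge=1)
    noise_cv: float = Field(default=0.05, ge=0.0)
    trace_noise_sd: float = Field(default=0.0, ge=0.0)
    sampling_rate: float = Field(default=20.0, gt=0.0)
    plate_noise_sd: float = Field(default=0.0, ge=0.0)


def _cell_rng(config: SimulationConfig, stream: int, cell: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream, cell]))


def _amplitude_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0.0:
        return np.ones(size)
    return np.maximum(rng.normal(1.0, cv, size), 0.0)


def half_log_ladder(center: float, n_points: int = 8, decades_each_side: float = 1.75) -> np.ndarray:
    """Half-log concentration ladder bracketing ``center`` symmetrically.

    Default spans >= 1.5 decades on each side of the anchor value,
    mirroring the curve spans typical of composite concentration-response
    figures.
    """
    lo = math.log10(center) - decades_each_side
    hi = math.log10(center) + decades_each_side
    return np.logspace(lo, hi, n_points)


def gen_crc_series(
    truth_ec50: float,
    truth_hill: float,
    top: float,
    concentrations: Sequence[float],
    config: SimulationConfig,
    construct: str = "WT",
    compound: str = "glutamate",
) -> list[ConcentrationSeries]:
    """Agonist concentration-response series for ``config.n_cells`` cells.

    The noiseless response at concentration c is top / (1 + (EC50/c)^N);
    each cell's responses are perturbed multiplicatively.
    """
    if truth_ec50 <= 0 or top <= 0 or truth_hill <= 0:
        raise ValueError("EC50, Hill slope and top must be positive")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly positive and ascending")
    expected = top * hill_response(conc, truth_ec50, truth_hill)
    out = []
    for i in range(config.n_cells):
        rng = _cell_rng(config, _STREAM_CRC, i)
        resp = expected * _amplitude_noise(rng, config.noise_cv, conc.size)
        out.append(
            ConcentrationSeries(
                cell_id=f"cell{i:03d}", construct=construct, compound=compound,
                role="agonist", concentration=conc.copy(), response=resp,
            )
        )
    return out


def gen_inhibition_series(
    truth_ic50: float,
    truth_hill: float,
    minimum: float,
    concentrations: Sequence[float],
    config: SimulationConfig,
    construct: str = "WT",
    compound: str = "Mg",
) -> list[ConcentrationSeries]:
    """Negative-modulator inhibition series (percent of unmodulated control).

    The noiseless response at modulator concentration m is
    (100 - minimum) / (1 + (m/IC50)^N) + minimum.
    """
    if truth_ic50 <= 0 or truth_hill <= 0:
        raise ValueError("IC50 and Hill slope must be positive")
    if not 0.0 <= minimum < 100.0:
        raise ValueError("minimum must lie in [0, 100)")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly positive and ascending")
    expected = inhibition_response(conc, truth_ic50, truth_hill, minimum)
    out = []
    for i in range(config.n_cells):
        rng = _cell_rng(config, _STREAM_INHIB, i)
        resp = expected * _amplitude_noise(rng, config.noise_cv, conc.size)
        out.append(
            ConcentrationSeries(
                cell_id=f"cell{i:03d}", construct=construct, compound=compound,
                role="inhibitor", concentration=conc.copy(), response=resp,
            )
        )
    return out


def decay_trace_model(
    time_ms: np.ndarray,
    peak: float,
    frac_fast: float,
    tau_fast: float,
    tau_slow: float,
    rise_tau: float,
    protocol: ApplicationProtocol,
    ss_frac: float = 1.0,
    desens_tau: float | None = None,
) -> np.ndarray:
    """Noiseless current-density time course (pA/pF, positive magnitude).

    Onset is a saturating exponential rise toward ``peak`` during the
    application window (instantaneous when rise_tau = 0), optionally relaxing
    toward ``ss_frac * peak`` with time constant ``desens_tau``; after agonist
    removal the current decays as
    peak * [f * exp(-t/tau_f) + (1-f) * exp(-t/tau_s)] anchored at the level
    reached at the end of the application (for prolonged applications the
    anchor equals ``peak`` to machine precision).
    """
    t0, t1 = protocol.application_start_ms, protocol.application_end_ms

    def envelope(ts: np.ndarray) -> np.ndarray:
        rel = ts - t0
        rise = 1.0 - np.exp(-rel / rise_tau) if rise_tau > 0 else np.ones_like(rel)
        if ss_frac < 1.0:
            if desens_tau is None or desens_tau <= 0:
                raise ValueError("desensitizing trace requires a positive desens_tau")
            rise = rise * (ss_frac + (1.0 - ss_frac) * np.exp(-rel / desens_tau))
        return peak * rise

    d = np.zeros_like(time_ms)
    during = (time_ms >= t0) & (time_ms <= t1)
    d[during] = envelope(time_ms[during])
    after = time_ms > t1
    anchor = float(envelope(np.array([t1]))[0])
    rel = time_ms[after] - t1
    d[after] = anchor * (
        frac_fast * np.exp(-rel / tau_fast) + (1.0 - frac_fast) * np.exp(-rel / tau_slow)
    )
    return d


def gen_decay_trace(
    peak: float,
    frac_fast: float,
    tau_fast: float,
    tau_slow: float,
    rise_tau: float,
    protocol: ApplicationProtocol,
    config: SimulationConfig,
    duration_ms: float | None = None,
    ss_frac: float = 1.0,
    desens_tau: float | None = None,
    cell: int = 0,
) -> CurrentTrace:
    """Sampled current trace from the bi-exponential decay model.

    ``peak`` is the peak current density (pA/pF); stored currents are
    negative (inward) in pA, scaled by the protocol capacitance, with
    additive Gaussian noise of SD ``config.trace_noise_sd``.  The trace spans
    from t = 0 through ``duration_ms`` (default: application end plus
    8 x tau_slow of tail, enough for deactivation fitting).
    """
    if peak < 0:
        raise ValueError("peak density must be non-negative")
    if not 0.0 <= frac_fast <= 1.0:
        raise ValueError("frac_fast must lie in [0, 1]")
    if tau_fast > tau_slow:
        raise ValueError("tau_fast must not exceed tau_slow")
    if tau_fast <= 0 or rise_tau < 0:
        raise ValueError("time constants must be positive (rise_tau may be 0)")
    if duration_ms is None:
        duration_ms = protocol.application_end_ms + max(8.0 * tau_slow, 100.0)
    if duration_ms < protocol.application_end_ms:
        raise ValueError("protocol window lies outside the requested trace span")
    dt = 1.0 / config.sampling_rate  # ms
    n = int(round(duration_ms / dt)) + 1
    time_ms = np.arange(n) * dt
    density = decay_trace_model(
        time_ms, peak, frac_fast, tau_fast, tau_slow, rise_tau, protocol,
        ss_frac=ss_frac, desens_tau=desens_tau,
    )
    current = -density * protocol.capacitance_pF
    if config.trace_noise_sd > 0:
        rng = _cell_rng(config, _STREAM_TRACE, cell)
        current = current + rng.normal(0.0, config.trace_noise_sd, n)
    return CurrentTrace(time_ms=time_ms, current_pA=current, protocol=protocol)


def gen_betalac_plate(
    surface_fraction: float,
    total_rate: float,
    background_rate: float,
    n_wells_per_condition: int,
    duration_min: int,
    config: SimulationConfig,
    construct: str = "WT",
    experiment_id: str = "exp0",
    experiment: int = 0,
) -> PlateAssay:
    """One reporter-assay experiment: surface, total and background wells.

    Surface wells ramp at background + surface_fraction * total_rate, total
    wells at background + total_rate, background wells at the background rate
    alone, one absorbance read per minute.  Per-well rate scatter uses
    ``config.noise_cv``; per-read absorbance noise uses
    ``config.plate_noise_sd``.
    """
    if total_rate < 0 or background_rate < 0:
        raise ValueError("rates must be non-negative")
    if not 0.0 <= surface_fraction <= 1.0:
        raise ValueError("surface_fraction must lie in [0, 1]")
    if duration_min < 3:
        raise ValueError("insufficient data: need at least 3 one-minute reads")
    if n_wells_per_condition < 1:
        raise ValueError("need at least one well per condition")
    time = np.arange(duration_min, dtype=float)
    nominal = {
        "surface": background_rate + surface_fraction * total_rate,
        "total": background_rate + total_rate,
        "background": background_rate,
    }
    wells: list[WellSeries] = []
    widx = 0
    for cond, rate in nominal.items():
        for _ in range(n_wells_per_condition):
            rng = _cell_rng(config, _STREAM_PLATE, (experiment << 16) | widx)
            well_rate = rate * float(_amplitude_noise(rng, config.noise_cv, 1)[0])
            od = 0.05 + well_rate * time
            if config.plate_noise_sd > 0:
                od = od + rng.normal(0.0, config.plate_noise_sd, time.size)
            wells.append(
                WellSeries(time_min=time.copy(), od486=od,
                           well=f"W{widx:02d}", condition=cond)
            )
            widx += 1
    return PlateAssay(wells=wells, construct=construct, experiment_id=experiment_id)


def gen_potentiation_pairs(
    truth_ratio: float,
    n: int,
    config: SimulationConfig,
    condition: str = "MTSEA",
    base_amplitude: float = 1.0,
) -> list[PotentiationPair]:
    """Before/after amplitude pairs with lognormal scatter around truth_ratio.

    The lognormal is mean-unbiased (sigma = config.noise_cv), so the sample
    mean ratio converges to ``truth_ratio``.  Baseline amplitudes (nA)
    scatter lognormally around ``base_amplitude``.
    """
    if truth_ratio <= 0:
        raise ValueError("truth_ratio must be positive")
    if n < 1:
        raise ValueError("need at least one pair")
    sigma = config.noise_cv
    out = []
    for i in range(n):
        rng = _cell_rng(config, _STREAM_PAIRS, i)
        before = base_amplitude * rng.lognormal(0.0, 0.3)
        if sigma > 0:
            ratio = truth_ratio * rng.lognormal(-0.5 * sigma * sigma, sigma)
        else:
            ratio = truth_ratio
        out.append(
            PotentiationPair(i_before=float(before), i_after=float(before * ratio),
                             cell_id=f"cell{i:03d}", condition=condition)
        )
    return out
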