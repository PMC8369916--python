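"""Quantification of whole-cell current traces.

Operations on sampled currents from voltage-clamped cells: baseline-corrected
peak and steady-state amplitudes (normalized to capacitance as current
densities, pA/pF), the I_SS/I_PEAK desensitization ratio, 10-90% rise time,
bi-exponential decay fitting with an amplitude-weighted time constant

    tau_w = (A_fast * tau_fast + A_slow * tau_slow) / (A_fast + A_slow)

and the charge-transfer integral (pA*ms/pF).  The deactivation time course
after rapid agonist removal approximates the decay of the synaptic current,
which is why tau_w enters the composite charge-transfer index.

Sign convention: inward currents are negative in stored traces; all reported
densities and integrals are magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ApplicationProtocol",
    "CurrentTrace",
    "BiExpFit",
    "AmplitudeResult",
    "RiseTimeResult",
    "KineticSummary",
    "measure_amplitudes",
    "rise_time_10_90",
    "fit_biexponential",
    "weighted_tau",
    "charge_transfer_integral",
    "normalize_iv",
    "summarize_trace",
]

BASELINE_MS = 50.0  # baseline segment preceding agonist application
NOISE_FLOOR_SIGMA = 3.0  # peak must exceed this multiple of baseline SD
F_TEST_ALPHA = 0.01  # 1-vs-2 exponential model selection


@dataclass
class ApplicationProtocol:
    """Agonist application metadata accompanying a trace.

    ``mode`` distinguishes prolonged (~1.5 s, steady state reached) from
    brief (~5 ms, synaptic-like) applications.
    """

    application_start_ms: float
    application_end_ms: float
    capacitance_pF: float
    mode: str = "prolonged"  # "prolonged" | "brief"
    holding_mV: float = -60.0
    sampling_khz: float = 20.0

    def __post_init__(self) -> None:
        if self.application_end_ms <= self.application_start_ms:
            raise ValueError("application_end must exceed application_start")
        if self.capacitance_pF <= 0:
            raise ValueError("capacitance must be positive")
        if self.mode not in ("prolonged", "brief"):
            raise ValueError(f"unknown application mode {self.mode!r}")


@dataclass
class CurrentTrace:
    """Uniformly sampled current with its application protocol."""

    time_ms: np.ndarray
    current_pA: np.ndarray
    protocol: ApplicationProtocol

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        if self.time_ms.shape != self.current_pA.shape or self.time_ms.ndim != 1:
            raise ValueError("time and current must be matching 1-D arrays")
        if self.time_ms.size < 2:
            raise ValueError("trace must contain at least two samples")
        dt = np.diff(self.time_ms)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trace must be uniformly sampled")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])


@dataclass
class BiExpFit:
    """Bi-exponential decay parameters; single-exponential fits are reported
    with both time constants equal and pct_fast = 100."""

    amp_fast: float
    amp_slow: float
    tau_fast: float
    tau_slow: float
    tau_w: float
    pct_fast: float
    rss: float
    converged: bool
    n_components: int = 2
    window: str = "deactivation"
    plateau: float = 0.0
    message: str = ""


@dataclass
class AmplitudeResult:
    peak_density: float  # pA/pF, magnitude
    ss_density: float
    iss_over_ipeak: float
    baseline_pA: float
    baseline_sd_pA: float
    responsive: bool
    peak_index: int


@dataclass
class RiseTimeResult:
    rise_ms: float
    flagged_nonmonotone: bool = False


@dataclass
class KineticSummary:
    peak_density: float
    ss_density: float
    iss_over_ipeak: float
    rise_10_90: float
    deactivation: BiExpFit | None
    charge_density: float
    responsive: bool


def _window_mask(trace: CurrentTrace) -> np.ndarray:
    p = trace.protocol
    return (trace.time_ms >= p.application_start_ms) & (trace.time_ms <= p.application_end_ms)


def measure_amplitudes(trace: CurrentTrace) -> AmplitudeResult:
    """Baseline-subtracted peak and steady-state current densities.

    Baseline is the mean of the 50 ms preceding application; peak is the
    extremum within the application window; steady state is the mean of the
    last 10% of the window.  A peak below 3x the baseline SD is flagged
    non-responsive.
    """
    p = trace.protocol
    base_mask = (trace.time_ms >= p.application_start_ms - BASELINE_MS) & (
        trace.time_ms < p.application_start_ms
    )
    if trace.time_ms[0] > p.application_start_ms - BASELINE_MS + trace.dt_ms:
        raise ValueError(f"trace must include >= {BASELINE_MS:g} ms of baseline before application")
    baseline = float(trace.current_pA[base_mask].mean())
    baseline_sd = float(trace.current_pA[base_mask].std(ddof=0))

    win = _window_mask(trace)
    if not win.any():
        raise ValueError("application window lies outside the trace span")
    corrected = trace.current_pA - baseline
    win_idx = np.flatnonzero(win)
    peak_local = int(np.argmax(np.abs(corrected[win])))
    peak_index = int(win_idx[peak_local])
    peak = float(abs(corrected[peak_index]))

    t_lo = p.application_end_ms - 0.1 * (p.application_end_ms - p.application_start_ms)
    ss_mask = win & (trace.time_ms >= t_lo)
    ss = float(np.abs(corrected[ss_mask].mean()))

    responsive = peak > NOISE_FLOOR_SIGMA * baseline_sd and peak > 0
    cap = p.capacitance_pF
    ratio = ss / peak if peak > 0 else math.nan
    return AmplitudeResult(
        peak_density=peak / cap,
        ss_density=ss / cap,
        iss_over_ipeak=ratio,
        baseline_pA=baseline,
        baseline_sd_pA=baseline_sd,
        responsive=responsive,
        peak_index=peak_index,
    )


def rise_time_10_90(trace: CurrentTrace) -> RiseTimeResult:
    """10-90% rise time of the onset, by linear interpolation between samples.

    Uses the first crossings of 10% and 90% of the peak on the rising phase;
    a rise that recrosses the 10% level before reaching 90% is handled by the
    first-crossing convention and flagged.
    """
    amps = measure_amplitudes(trace)
    if not amps.responsive:
        raise ValueError("no identified peak: trace is non-responsive")
    p = trace.protocol
    base = amps.baseline_pA
    y = np.abs(trace.current_pA - base)
    start = int(np.searchsorted(trace.time_ms, p.application_start_ms))
    seg = y[start : amps.peak_index + 1]
    t_seg = trace.time_ms[start : amps.peak_index + 1]
    peak = y[amps.peak_index]

    def first_crossing(level: float) -> float:
        above = seg >= level
        idx = int(np.argmax(above))
        if not above.any():
            raise ValueError("rising phase never reaches threshold")
        if idx == 0:
            return float(t_seg[0])
        y0, y1 = seg[idx - 1], seg[idx]
        t0, t1 = t_seg[idx - 1], t_seg[idx]
        return float(t0 + (level - y0) / (y1 - y0) * (t1 - t0))

    t10 = first_crossing(0.1 * peak)
    t90 = first_crossing(0.9 * peak)
    # non-monotone: signal drops back below the 10% level between crossings
    i10 = int(np.searchsorted(t_seg, t10))
    i90 = int(np.searchsorted(t_seg, t90))
    flagged = bool(np.any(seg[i10:i90] < 0.1 * peak)) if i90 > i10 else False
    rise = max(t90 - t10, trace.dt_ms)  # resolution floor: one sample interval
    return RiseTimeResult(rise_ms=float(rise), flagged_nonmonotone=flagged)


def _fit_exp_sum(t: np.ndarray, y: np.ndarray, n_comp: int, with_plateau: bool,
                 tau_init: float) -> tuple[lmfit.minimizer.MinimizerResult, float]:
    params = lmfit.Parameters()
    y0 = max(float(y[0]), 1e-12)
    tmax = float(t[-1]) if t[-1] > 0 else 1.0
    if n_comp == 1:
        params.add("a1", value=y0, min=0.0)
        params.add("tau1", value=tau_init, min=1e-6, max=100 * tmax)
    else:
        params.add("a1", value=0.6 * y0, min=0.0)
        params.add("tau1", value=tau_init / 3.0, min=1e-6, max=100 * tmax)
        params.add("a2", value=0.4 * y0, min=0.0)
        params.add("tau2", value=tau_init * 3.0, min=1e-6, max=100 * tmax)
    if with_plateau:
        params.add("c", value=float(max(y[-1], 0.0)), min=0.0)

    def residual(p):
        model = p["a1"].value * np.exp(-t / p["tau1"].value)
        if n_comp == 2:
            model = model + p["a2"].value * np.exp(-t / p["tau2"].value)
        if with_plateau:
            model = model + p["c"].value
        return model - y

    res = lmfit.minimize(residual, params, method="least_squares",
                         ftol=1e-15, xtol=1e-15, gtol=1e-15)
    rss = float(np.sum(res.residual ** 2))
    return res, rss


def fit_biexponential(trace: CurrentTrace, window: str = "deactivation") -> BiExpFit:
    """Fit a sum of exponentials to the decaying phase of a trace.

    ``window='deactivation'`` fits from one sample after agonist removal to
    the end of the trace (the first post-application sample is skipped to
    avoid the solution-exchange artifact).  ``window='desensitization'`` fits
    from the peak to the end of application and includes a plateau term.
    The two-component fit is kept only if it improves on a single exponential
    by an F-test at alpha = 0.01; otherwise the single-exponential fallback
    is reported with pct_fast = 100 and both time constants equal.
    """
    if window not in ("deactivation", "desensitization"):
        raise ValueError(f"unknown window {window!r}")
    p = trace.protocol
    amps = measure_amplitudes(trace)
    y_full = np.abs(trace.current_pA - amps.baseline_pA)

    if window == "deactivation":
        start = int(np.searchsorted(trace.time_ms, p.application_end_ms, side="right"))
        start += 1  # skip the exchange-artifact sample
        sel = slice(start, trace.time_ms.size)
        with_plateau = False
    else:
        end = int(np.searchsorted(trace.time_ms, p.application_end_ms, side="right"))
        sel = slice(amps.peak_index, end)
        with_plateau = True

    t = trace.time_ms[sel]
    y = y_full[sel]
    if t.size < 8:
        raise ValueError("decay window too short to fit")
    t = t - t[0]

    # non-decaying window: flag instead of fitting noise
    third = t.size // 3
    if y[:third].mean() <= y[-third:].mean() + 1e-12:
        return BiExpFit(math.nan, math.nan, math.nan, math.nan, math.nan, math.nan,
                        math.inf, False, window=window, message="window does not decay")

    # crude initial tau from the time to fall to 1/e of the initial level
    target = (y[0] - y[-1]) / math.e + y[-1]
    below = np.flatnonzero(y <= target)
    tau0 = float(t[below[0]]) if below.size else float(t[-1] / 3.0)
    tau0 = max(tau0, 2 * trace.dt_ms)

    res1, rss1 = _fit_exp_sum(t, y, 1, with_plateau, tau0)
    res2, rss2 = _fit_exp_sum(t, y, 2, with_plateau, tau0)

    n = t.size
    k2 = 4 + (1 if with_plateau else 0)
    use_two = False
    if rss2 > 0 and rss2 < rss1:
        f_stat = ((rss1 - rss2) / 2.0) / (rss2 / max(n - k2, 1))
        p_val = float(stats.f.sf(f_stat, 2, max(n - k2, 1)))
        use_two = p_val < F_TEST_ALPHA
    elif rss2 == 0.0 and rss1 > 0:
        use_two = True

    plateau = 0.0
    if use_two:
        pr = res2.params
        a1, tau1 = float(pr["a1"].value), float(pr["tau1"].value)
        a2, tau2 = float(pr["a2"].value), float(pr["tau2"].value)
        if with_plateau:
            plateau = float(pr["c"].value)
        if tau1 > tau2:  # enforce tau_fast <= tau_slow
            a1, a2, tau1, tau2 = a2, a1, tau2, tau1
        total = a1 + a2
        if total <= 0:
            return BiExpFit(a1, a2, tau1, tau2, math.nan, math.nan, rss2, False,
                            window=window, message="degenerate amplitudes")
        tau_w = (a1 * tau1 + a2 * tau2) / total
        return BiExpFit(a1, a2, tau1, tau2, tau_w, 100.0 * a1 / total, rss2,
                        bool(res2.success), 2, window, plateau)
    pr = res1.params
    a1, tau1 = float(pr["a1"].value), float(pr["tau1"].value)
    if with_plateau:
        plateau = float(pr["c"].value)
    return BiExpFit(a1, 0.0, tau1, tau1, tau1, 100.0, rss1, bool(res1.success),
                    1, window, plateau)


def weighted_tau(fit: BiExpFit) -> float:
    """Amplitude-weighted time constant of a converged bi-exponential fit."""
    if not fit.converged:
        raise ValueError("weighted_tau requires a converged fit")
    total = fit.amp_fast + fit.amp_slow
    return (fit.amp_fast * fit.tau_fast + fit.amp_slow * fit.tau_slow) / total


def charge_transfer_integral(trace: CurrentTrace) -> tuple[float, str | None]:
    """Trapezoidal charge-transfer integral, pA*ms/pF.

    Integrates the baseline-subtracted current density magnitude from
    application start to the end of the trace.  If the current has not
    decayed below 5% of peak at the trace end, a truncation warning is
    returned alongside the value.
    """
    p = trace.protocol
    amps = measure_amplitudes(trace)
    y = np.abs(trace.current_pA - amps.baseline_pA) / p.capacitance_pF
    mask = trace.time_ms >= p.application_start_ms
    value = float(np.trapezoid(y[mask], trace.time_ms[mask]))
    warning = None
    if amps.peak_density > 0 and y[-1] > 0.05 * amps.peak_density:
        warning = "tail unterminated: current > 5% of peak at trace end"
    return value, warning


def normalize_iv(
    records: Sequence[tuple[float, float]] | pd.DataFrame,
    reference_mV: float = -90.0,
) -> pd.DataFrame:
    """Normalize a current-voltage table to the amplitude at a reference voltage.

    ``records`` is a sequence of (holding_mV, amplitude) or a DataFrame with
    those columns.  All amplitudes are divided by the amplitude at
    ``reference_mV`` (exact match required).
    """
    if isinstance(records, pd.DataFrame):
        df = records.rename(columns=lambda c: c.strip()).copy()
    else:
        df = pd.DataFrame(records, columns=["holding_mV", "amplitude"])
    ref = df.loc[np.isclose(df["holding_mV"], reference_mV), "amplitude"]
    if ref.empty:
        raise ValueError(f"reference voltage {reference_mV} mV not present in records")
    ref_amp = float(ref.iloc[0])
    if ref_amp == 0:
        raise ValueError("reference amplitude is zero; cannot normalize")
    df["normalized"] = df["amplitude"] / ref_amp
    return df


def summarize_trace(trace: CurrentTrace, fit_deactivation: bool = True) -> KineticSummary:
    """One-call kinetic summary of a trace (amplitudes, rise, decay, charge)."""
    amps = measure_amplitudes(trace)
    deact = None
    rise = math.nan
    if amps.responsive:
        rise = rise_time_10_90(trace).rise_ms
        if fit_deactivation:
            deact = fit_biexponential(trace, "deactivation")
    charge, _ = charge_transfer_integral(trace)
    return KineticSummary(
        peak_density=amps.peak_density,
        ss_density=amps.ss_density,
        iss_over_ipeak=amps.iss_over_ipeak,
        rise_10_90=rise,
        deactivation=deact,
        charge_density=charge,
        responsive=amps.responsive,
    )
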