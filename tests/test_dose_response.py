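"""Hill and inhibition-with-plateau fitting: point values, oracle
equivalence against a dense grid search, monotonicity, and noisy recovery."""

import numpy as np
import pytest

from nmdarprof.dose_response import (
    CRCFitConfig,
    ConcentrationSeries,
    composite_curve,
    fit_activation,
    fit_inhibition,
    hill_response,
    inhibition_response,
)
from nmdarprof.synthetic_data import (
    SimulationConfig,
    gen_crc_series,
    gen_inhibition_series,
    half_log_ladder,
)


class TestPointValues:
    def test_half_maximal_at_ec50(self):
        for n in (0.5, 1.0, 1.5, 3.0):
            assert hill_response(2e-6, 2e-6, n) == pytest.approx(0.5, rel=1e-12)

    def test_hill_direct_evaluation(self):
        # 1 / (1 + 1.8/3) with unit slope
        assert hill_response(3e-6, 1.8e-6, 1.0) == pytest.approx(0.625, rel=1e-12)

    def test_hill_saturates_to_one(self):
        assert hill_response(1.0, 1e-6, 1.5) == pytest.approx(1.0, abs=1e-8)

    def test_hill_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            hill_response(0.0, 1e-6, 1.5)
        with pytest.raises(ValueError):
            hill_response(1e-6, -1e-6, 1.5)

    def test_inhibition_at_zero_and_midpoint(self):
        assert inhibition_response(0.0, 2e-5, 1.0, 20.0) == pytest.approx(100.0)
        assert inhibition_response(2e-5, 2e-5, 1.0, 20.0) == pytest.approx(60.0)

    def test_inhibition_direct_evaluation(self):
        # minimum 0, IC50 20 uM, N=1, c = 1000 uM: 100/51
        assert inhibition_response(1e-3, 2e-5, 1.0, 0.0) == pytest.approx(100.0 / 51.0, rel=1e-12)

    def test_inhibition_rejects_bad_minimum(self):
        with pytest.raises(ValueError):
            inhibition_response(1e-6, 1e-6, 1.0, 100.0)


def _series(conc, resp, role="agonist"):
    return ConcentrationSeries("c0", "WT", "glutamate" if role == "agonist" else "Mg",
                               role, np.asarray(conc), np.asarray(resp))


class TestFitActivation:
    def test_three_point_series_rejected(self):
        s = _series([1e-6, 1e-5, 1e-4], [10.0, 50.0, 90.0])
        with pytest.raises(ValueError, match="distinct concentrations"):
            fit_activation(s)

    def test_flat_series_flagged_nonconverged(self):
        s = _series(np.logspace(-7, -3, 6), np.full(6, 50.0))
        fit = fit_activation(s)
        assert not fit.converged

    def test_grid_oracle_equivalence(self):
        """The optimizer matches a dense 2-D (log-EC50 x Hill) grid search.

        For each grid point the optimal top is the closed-form linear
        least-squares amplitude, so the grid is an independent oracle for the
        nonlinear fit.  Agreement required within one grid step
        (0.01 decade x 0.01).
        """
        rng = np.random.default_rng(42)
        conc = np.logspace(-7, -4, 6)
        truth = 90.0 * hill_response(conc, 4e-6, 1.3)
        y = truth * (1.0 + 0.06 * rng.standard_normal(6))
        s = _series(conc, np.abs(y))
        fit = fit_activation(s)

        log_grid = np.arange(-8.0, -3.0, 0.01)
        hill_grid = np.arange(0.3, 5.0, 0.01)
        h = 1.0 / (1.0 + (10.0 ** log_grid[:, None, None] / conc[None, None, :])
                   ** hill_grid[None, :, None])
        top_hat = (h * y).sum(axis=2) / (h * h).sum(axis=2)
        rss = ((top_hat[:, :, None] * h - y) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        assert abs(np.log10(fit.ec50) - log_grid[i]) <= 0.01 + 1e-9
        assert abs(fit.hill - hill_grid[j]) <= 0.01 + 1e-9
        assert fit.rss <= rss[i, j] + 1e-9

    def test_fitted_curve_monotone_on_data_grid(self):
        cfg = SimulationConfig(seed=2, n_cells=1, noise_cv=0.05)
        s = gen_crc_series(6.4e-6, 1.5, 100.0, half_log_ladder(6.4e-6), cfg)[0]
        fit = fit_activation(s)
        curve = fit.top * hill_response(s.concentration, fit.ec50, fit.hill)
        assert np.all(np.diff(curve) > 0)

    def test_noisy_recovery_median_error_under_5pct(self):
        """Median relative error of the aggregated (mean-of-cells) EC50 < 5%
        across replicate simulated experiments at 5% amplitude noise."""
        errs = []
        for rep in range(20):
            cfg = SimulationConfig(seed=1000 + rep, n_cells=10, noise_cv=0.05)
            series = gen_crc_series(105e-6, 1.5, 100.0, np.logspace(-7, -3, 8), cfg)
            fits = [fit_activation(s) for s in series]
            assert all(f.converged for f in fits)
            est = np.mean([f.ec50 for f in fits])
            errs.append(abs(est - 105e-6) / 105e-6)
        assert np.median(errs) < 0.05


class TestFitInhibition:
    def test_noiseless_recovery_with_plateau(self):
        cfg = SimulationConfig(seed=1, n_cells=1, noise_cv=0.0)
        s = gen_inhibition_series(8.5e-9, 1.0, 37.0, half_log_ladder(8.5e-9), cfg)[0]
        fit = fit_inhibition(s)
        assert fit.converged
        assert fit.ic50 == pytest.approx(8.5e-9, rel=1e-6)
        assert fit.minimum == pytest.approx(37.0, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)

    def test_uninhibited_series_flagged(self):
        s = _series(np.logspace(-9, -5, 6), np.full(6, 100.0), role="inhibitor")
        fit = fit_inhibition(s)
        assert not fit.converged

    def test_wide_ci_warning_without_plateau_coverage(self):
        cfg = SimulationConfig(seed=1, n_cells=1, noise_cv=0.0)
        conc = np.logspace(-9, -7.2, 5)  # all below IC50 = 1e-6
        s = gen_inhibition_series(1e-6, 1.0, 0.0, conc, cfg)[0]
        fit = fit_inhibition(s)
        if fit.converged:
            assert fit.warning is not None

    def test_fitted_curve_monotone_decreasing(self):
        cfg = SimulationConfig(seed=3, n_cells=1, noise_cv=0.05)
        s = gen_inhibition_series(19e-6, 1.0, 0.0, half_log_ladder(19e-6), cfg)[0]
        fit = fit_inhibition(s)
        curve = inhibition_response(s.concentration, fit.ic50, fit.hill, fit.minimum)
        assert np.all(np.diff(curve) < 0)


class TestCompositeCurve:
    def test_identical_cells_compose_to_single_cell(self):
        cfg = SimulationConfig(seed=1, n_cells=1, noise_cv=0.0)
        base = gen_crc_series(2e-6, 1.5, 100.0, half_log_ladder(2e-6), cfg)[0]
        cells = [
            ConcentrationSeries(f"c{i}", "WT", "glycine", "agonist",
                                base.concentration.copy(), base.response.copy())
            for i in range(3)
        ]
        comp = composite_curve(cells)
        np.testing.assert_allclose(
            comp.table["mean"].to_numpy(),
            100.0 * base.response / fit_activation(base).top,
            rtol=1e-9,
        )
        assert comp.ec50_stats.mean == pytest.approx(2e-6, rel=1e-6)

    def test_mean_ec50_recovers_truth_at_many_cells(self):
        cfg = SimulationConfig(seed=21, n_cells=12, noise_cv=0.05)
        cells = gen_crc_series(2e-6, 1.5, 100.0, half_log_ladder(2e-6), cfg,
                               compound="glycine")
        comp = composite_curve(cells)
        assert comp.ec50_stats.mean == pytest.approx(2e-6, rel=0.07)
        assert comp.ec50_stats.ci95_low < 2e-6 < comp.ec50_stats.ci95_high

    def test_single_cell_degenerate_flag(self):
        cfg = SimulationConfig(seed=1, n_cells=1, noise_cv=0.0)
        cells = gen_crc_series(2e-6, 1.5, 100.0, half_log_ladder(2e-6), cfg)
        comp = composite_curve(cells)
        assert comp.degenerate

    def test_mixed_constructs_rejected(self):
        cfg = SimulationConfig(seed=1, n_cells=1, noise_cv=0.0)
        a = gen_crc_series(2e-6, 1.5, 100.0, half_log_ladder(2e-6), cfg, construct="WT")
        b = gen_crc_series(2e-6, 1.5, 100.0, half_log_ladder(2e-6), cfg, construct="P532H")
        with pytest.raises(ValueError, match="mixed"):
            composite_curve(a + b)
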