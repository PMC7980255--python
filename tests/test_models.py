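"""Regime model evaluation, ε*, fitting, window scanning, classification."""

import math

import numpy as np
import pytest

from superstruct import (
    EpsilonGrid,
    SuperStructureCurve,
    build_epsilon_grid,
    classify_regime,
    epsilon_star,
    eval_exponential,
    eval_poisson_cluster,
    eval_poisson_intra,
    fit_regime,
    normalize_lambda,
    scan_window,
)


class TestModelEvaluation:
    @pytest.mark.parametrize("m", [0, 1, 2, 5])
    @pytest.mark.parametrize("rho", [100.0, 16000.0])
    def test_intra_model_is_one_at_zero(self, m, rho):
        assert eval_poisson_intra(0.0, rho, m) == 1.0

    def test_intra_series_value_at_x_one(self):
        # x = pi*rho*eps^2 = 1 with m=2: e^-1 * (1 + 1/2 + 1/6)
        rho_um2 = 1e6 / math.pi  # 1 nm^-2 / pi -> x = eps^2
        assert eval_poisson_intra(1.0, rho_um2, 2) == pytest.approx(
            math.exp(-1) * (1 + 0.5 + 1 / 6), rel=1e-12
        )

    def test_cluster_model_prefactor_at_zero(self):
        assert eval_poisson_cluster(0.0, 8.2, f=0.013) == pytest.approx(0.013)

    def test_exponential_values(self):
        assert eval_exponential(30.0, 0.8, 30.0) == pytest.approx(0.8 / math.e)
        assert eval_exponential(0.0, 0.8, 30.0) == pytest.approx(0.8)

    def test_log_exponential_is_linear(self):
        eps = np.linspace(0, 100, 11)
        logs = np.log(eval_exponential(eps, 2.0, 25.0))
        slopes = np.diff(logs) / np.diff(eps)
        np.testing.assert_allclose(slopes, -1 / 25.0, rtol=1e-12)

    @pytest.mark.parametrize(
        "evaluate, eps_hi",
        [
            (lambda e: eval_poisson_intra(e, 16000.0, 2), 60.0),
            (lambda e: eval_poisson_cluster(e, 8.2, 1.0, 1), 500.0),
            (lambda e: eval_exponential(e, 1.0, 30.0), 500.0),
        ],
    )
    def test_models_strictly_decreasing(self, evaluate, eps_hi):
        # ranges chosen so the decays stay above floating-point underflow
        eps = np.linspace(1.0, eps_hi, 200)
        values = np.asarray(evaluate(eps))
        assert (np.diff(values) < 0).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            eval_poisson_intra(1.0, -5.0)
        with pytest.raises(ValueError):
            eval_exponential(1.0, 1.0, 0.0)


class TestEpsilonStar:
    def test_printed_low_density_value(self):
        assert round(epsilon_star(2000.0)) == 38

    def test_printed_high_density_value(self):
        assert epsilon_star(100000.0) == pytest.approx(5.35, abs=0.01)

    def test_closed_form_unit_case(self):
        # rho = 9/pi nm^-2 makes 3/sqrt(pi*rho) exactly 1 nm
        assert epsilon_star(9 / math.pi * 1e6) == pytest.approx(1.0, rel=1e-12)

    def test_non_positive_density_rejected(self):
        with pytest.raises(ValueError):
            epsilon_star(0.0)


def _curve_from_model(grid_values, y, nloc=10**6):
    grid = EpsilonGrid.from_values(grid_values)
    nc = np.round(np.asarray(y) * nloc).astype(np.int64)
    nc = np.minimum.accumulate(nc)  # guard rounding against monotonicity
    return SuperStructureCurve(grid=grid, nc=nc, nloc=nloc)


class TestFitRegime:
    def test_exact_exponential_recovery(self):
        eps = np.linspace(0, 100, 50)
        curve = _curve_from_model(eps, 0.8 * np.exp(-eps / 30.0))
        fit = fit_regime(curve, (0, 100), "exponential")
        assert fit.params["lam"] == pytest.approx(30.0, rel=1e-4)
        assert fit.params["g"] == pytest.approx(0.8, rel=1e-4)

    def test_exact_poisson_intra_recovery(self):
        eps = np.linspace(0, 4, 40)
        curve = _curve_from_model(eps, eval_poisson_intra(eps, 16000.0, 2))
        fit = fit_regime(curve, (0, 4), "poisson_intra")
        assert fit.params["rho_em"] == pytest.approx(16000.0, rel=1e-3)

    def test_exact_poisson_cluster_recovery(self):
        eps = np.linspace(50, 300, 60)
        curve = _curve_from_model(
            eps, eval_poisson_cluster(eps, 8.2, 0.0125, 1)
        )
        fit = fit_regime(curve, (50, 300), "poisson_cluster")
        assert fit.params["rho_cl"] == pytest.approx(8.2, rel=1e-3)
        assert fit.params["f"] == pytest.approx(0.0125, rel=1e-3)

    def test_standard_dataset_exponential_window(self, standard_curve):
        fit = fit_regime(standard_curve, (15, 60), "exponential")
        assert fit.params["lam"] > 0
        assert fit.r2 > 0.85

    def test_too_few_points_rejected(self, standard_curve):
        with pytest.raises(ValueError, match="4"):
            fit_regime(standard_curve, (15, 19), "exponential")

    @pytest.mark.parametrize("rho", [2000.0, 10000.0, 100000.0])
    def test_uniform_disc_recovers_density(self, rho):
        # one idealized cluster: points uniform in a disc; the intra-cluster
        # model fitted below the natural scale k0 recovers the density
        from superstruct import build_epsilon_grid, simulate_uniform_cluster, superstructure_curve

        k0 = 1 / math.sqrt(math.pi * rho * 1e-6)
        r_cl = math.sqrt(5000 / (math.pi * rho * 1e-6))
        table = simulate_uniform_cluster(5000, r_cl, seed=61)
        grid = build_epsilon_grid([(0, 2 * k0, k0 / 40)])
        curve = superstructure_curve(table, grid)
        fit = fit_regime(curve, (0, 0.75 * k0), "poisson_intra")
        assert fit.params["rho_em"] == pytest.approx(rho, rel=0.10)


class TestScanAndClassify:
    def _piecewise_curve(self):
        # Poisson head below 20 nm, exact exponential (lam=15) on [20, 80],
        # slow Poisson tail beyond; pieces joined continuously
        eps = np.arange(0, 101, 2.0)
        rho_head = 3.0 / (math.pi * 400e-6)  # x(20 nm) = 3
        head = np.asarray(eval_poisson_intra(eps, rho_head, 2))
        y20 = eval_poisson_intra(20.0, rho_head, 2)
        body = y20 * np.exp(-(eps - 20.0) / 15.0)
        y80 = y20 * math.exp(-4.0)
        tail = y80 * np.exp(-math.pi * 20e-6 * (eps**2 - 6400.0))
        y = np.where(eps < 20, head, np.where(eps <= 80, body, tail))
        return _curve_from_model(eps, y)

    def test_scan_finds_exponential_window(self):
        curve = self._piecewise_curve()
        window, fit = scan_window(curve, "exponential", 5, (0, 100))
        assert window[0] <= 25 and window[1] >= 75
        assert fit.params["lam"] == pytest.approx(15.0, rel=0.05)

    def test_pure_exponential_selects_widest_window(self):
        eps = np.linspace(0, 100, 26)
        curve = _curve_from_model(eps, np.exp(-eps / 40.0))
        window, _ = scan_window(curve, "exponential", 5, (0, 100))
        assert window == (0.0, 100.0)

    def test_short_search_range_rejected(self, standard_curve):
        with pytest.raises(ValueError, match="min_points"):
            scan_window(standard_curve, "exponential", 10, (15, 25))

    def test_exact_exponential_classified(self):
        eps = np.linspace(10, 100, 40)
        curve = _curve_from_model(eps, 0.5 * np.exp(-eps / 25.0))
        out = classify_regime(curve, (10, 100))
        assert out["kind"] == "exponential"
        assert out["fits"]["exponential"].chi2 < out["fits"]["poisson"].chi2

    def test_exact_poisson_classified(self):
        eps = np.linspace(50, 250, 40)
        curve = _curve_from_model(eps, eval_poisson_cluster(eps, 10.0, 0.01, 1))
        assert classify_regime(curve, (50, 250))["kind"] == "poisson"


class TestNormalizeLambda:
    def test_worked_example(self):
        nd = normalize_lambda(50.0, 8.2)
        assert nd.lam_star == pytest.approx(0.050 * 2.8636, abs=1e-4)

    def test_quadrupled_density_doubles_lambda_star(self):
        a = normalize_lambda(50.0, 8.2)
        b = normalize_lambda(50.0, 4 * 8.2)
        assert b.lam_star == pytest.approx(2 * a.lam_star)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            normalize_lambda(0.0, 8.2)
        with pytest.raises(ValueError):
            normalize_lambda(10.0, -1.0)
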