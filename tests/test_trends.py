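import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import expit

from ma_gxe import simulate, trends
from ma_gxe.io import ValidationError
from ma_gxe.trends import fit_component_trend, fit_proportion_trend

TEMPS = np.arange(23.0, 42.0, 2.0)


def grid_likelihood_oracle(counts, total, temps, iterations=8):
    """Direct maximization of the binomial log-likelihood on a refining grid.

    Independent of any IRLS machinery; works on the centered-temperature
    scale and returns (intercept, slope) back on the raw scale.
    """
    counts = np.asarray(counts, float)
    temps = np.asarray(temps, float)
    tc = temps - temps.mean()

    def loglik(a, b):
        eta = a + b * tc
        # log C(n,k) terms are constant in (a, b)
        return float(np.sum(counts * eta - total * np.log1p(np.exp(eta))))

    a_lo, a_hi, b_lo, b_hi = -20.0, 20.0, -3.0, 3.0
    best = (0.0, 0.0)
    for _ in range(iterations):
        a_grid = np.linspace(a_lo, a_hi, 41)
        b_grid = np.linspace(b_lo, b_hi, 41)
        values = np.array([[loglik(a, b) for b in b_grid] for a in a_grid])
        ia, ib = np.unravel_index(np.argmax(values), values.shape)
        best = (a_grid[ia], b_grid[ib])
        da = (a_hi - a_lo) / 40.0
        db = (b_hi - b_lo) / 40.0
        a_lo, a_hi = best[0] - 2 * da, best[0] + 2 * da
        b_lo, b_hi = best[1] - 2 * db, best[1] + 2 * db
    a, b = best
    return a - b * temps.mean(), b


class TestComponentTrend:
    def test_noiseless_parabola_recovery(self):
        values = 2.0 - 0.1 * (TEMPS - 32.0) ** 2
        fit = fit_component_trend(values, TEMPS)
        assert fit.coefficients["quadratic_T"] == pytest.approx(-0.1, abs=1e-8)
        # expanded raw-scale terms: 2 - 0.1 T^2 + 6.4 T - 102.4
        assert fit.coefficients["linear_T"] == pytest.approx(6.4, abs=1e-7)
        assert fit.coefficients["intercept"] == pytest.approx(-100.4, abs=1e-5)
        assert np.max(np.abs(fit.fitted - values)) < 1e-8
        assert fit.retained_terms == ("linear_T", "quadratic_T")

    def test_constant_values_reduce_to_intercept(self):
        fit = fit_component_trend(np.full_like(TEMPS, 0.7), TEMPS)
        assert fit.retained_terms == ()
        assert fit.coefficients == {"intercept": pytest.approx(0.7)}
        assert np.allclose(fit.fitted, 0.7)

    def test_pure_linear_drops_quadratic_only(self):
        rng = np.random.default_rng(5)
        values = 0.01 * TEMPS + rng.normal(0, 1e-4, TEMPS.size)
        fit = fit_component_trend(values, TEMPS)
        assert fit.retained_terms == ("linear_T",)
        assert fit.coefficients["linear_T"] == pytest.approx(0.01, rel=1e-2)

    def test_u_shaped_component_keeps_quadratic(self):
        # strong deficit curvature, tiny interaction: total variance is
        # dominated by sigma2_G ~ Var(delta) * lambda(T)^2, a U around T_mid
        cfg = simulate.SimulationConfig(
            d2=0.02, sigma_eta=0.005, omega0=0.002, omega1=0.0002
        )
        from ma_gxe import gxe

        table, _ = simulate.simulate_scores(cfg, seed=3)
        comps = gxe.partition_all(table)
        totals = np.array([c.total for c in comps])
        fit = fit_component_trend(totals, TEMPS)
        assert "quadratic_T" in fit.retained_terms
        quad_test = next(t for t in fit.terms if t.term == "quadratic_T")
        assert quad_test.statistic > sps.f.ppf(0.95, 1, TEMPS.size - 3)
        assert quad_test.estimate > 0  # opens upward: smallest at mid temperatures
        # cross-check full-model coefficients against generic least squares
        beta = np.polyfit(TEMPS, totals, 2)
        assert quad_test.estimate == pytest.approx(beta[0], rel=1e-6)

    def test_centering_invariance(self):
        rng = np.random.default_rng(12)
        values = 0.5 - 0.02 * (TEMPS - 30.0) ** 2 + rng.normal(0, 0.05, TEMPS.size)
        fit1 = fit_component_trend(values, TEMPS)
        fit2 = fit_component_trend(values, TEMPS - 10.0)
        assert np.allclose(fit1.fitted, fit2.fitted, atol=1e-8)
        for t1, t2 in zip(fit1.terms, fit2.terms):
            assert t1.statistic == pytest.approx(t2.statistic, rel=1e-8)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(13)
        values = rng.normal(size=TEMPS.size)
        fit = fit_component_trend(values, TEMPS)
        resid = values - fit.fitted
        tc = TEMPS - TEMPS.mean()
        for col in (np.ones_like(tc), tc, tc**2)[: fit.model_df]:
            assert abs(resid @ col) < 1e-8 * np.linalg.norm(values) * np.linalg.norm(col)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_component_trend([1.0, 2.0, 3.0], [23.0, 25.0, 27.0])


class TestProportionTrend:
    def test_identical_proportions_have_no_trend(self):
        fit = fit_proportion_trend([4] * 10, 10, TEMPS)
        assert fit.lr_chi2 == pytest.approx(0.0, abs=1e-8)
        assert fit.slope == pytest.approx(0.0, abs=1e-6)

    def test_logistic_recovery_against_grid_oracle(self):
        alpha_true, beta_true = -14.4, 0.45
        total = 1000
        counts = np.round(total * expit(alpha_true + beta_true * TEMPS))
        fit = fit_proportion_trend(counts, total, TEMPS)
        a_or, b_or = grid_likelihood_oracle(counts, total, TEMPS)
        assert fit.slope == pytest.approx(b_or, rel=1e-3)
        assert fit.slope == pytest.approx(beta_true, rel=0.05)
        assert fit.coefficients["intercept"] == pytest.approx(a_or, rel=1e-3)
        assert fit.lr_p < 1e-6

    def test_separation_is_flagged_not_fitted(self):
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_proportion_trend([0] * 10, 10, TEMPS)
        assert fit.separation
        assert fit.slope == 0.0

    def test_quadratic_not_added_when_useless(self):
        counts = np.round(10 * expit(-0.3 * (TEMPS - 31.0)))
        fit = fit_proportion_trend(counts, 10, TEMPS)
        quad = next(t for t in fit.terms if t.term == "quadratic_T")
        assert not quad.retained
        assert "quadratic" in " ".join(fit.notes)

    def test_centering_invariance(self):
        counts = [1, 1, 2, 3, 4, 4, 6, 7, 8, 9]
        fit1 = fit_proportion_trend(counts, 10, TEMPS)
        fit2 = fit_proportion_trend(counts, 10, TEMPS + 100.0)
        assert np.allclose(fit1.fitted, fit2.fitted, atol=1e-8)
        assert fit1.lr_chi2 == pytest.approx(fit2.lr_chi2, abs=1e-8)

    def test_score_equations_satisfied_at_optimum(self):
        # gradient of the binomial log-likelihood at the IRLS solution
        counts = np.array([0, 1, 1, 2, 4, 5, 6, 8, 9, 9], float)
        fit = fit_proportion_trend(counts, 10, TEMPS)
        p = fit.predict(TEMPS)
        tc = TEMPS - TEMPS.mean()
        grad = np.array([np.sum(counts - 10 * p), np.sum((counts - 10 * p) * tc)])
        assert np.linalg.norm(grad) < 1e-6

    def test_monotone_simulated_counts_give_positive_slope(self, sim_scores):
        from ma_gxe import classify

        table, _ = sim_scores
        results = classify.classify_table(table, [classify.LossThreshold("0.95", 0.95)])
        counts = [
            sum(
                1
                for r in results
                if r.temperature_c == t and r.category == classify.RESOURCE_DEPENDENT
            )
            for t in table.design.temperatures
        ]
        fit = fit_proportion_trend(counts, 10, np.array(table.design.temperatures))
        assert fit.slope_sign == 1
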