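import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import optimize

from conftest import well_conditioned_spec
from dosecurve.design import transform_doses
from dosecurve.models import fit_gam, fit_rlm
from dosecurve.potency import (bootstrap_se_xc50, classify_direction,
                               delta_se_xc50, estimate_potency,
                               fitted_extrema, max_effect_with_se,
                               percent_max_inhibition, run_potency, xc50,
                               xc50_linear)
from dosecurve.simulate import simulate_experiment


@pytest.fixture(scope="module")
def design():
    doses = np.repeat(10.0 / (10 ** 0.5) ** np.arange(8)[::-1], 3)
    return transform_doses(np.concatenate([[0.0] * 6, doses]))


def _sigmoid_fit(design, seed=0, emax=-1.5, ec50=-1.0, slope=1.0, sd=0.05):
    rng = np.random.default_rng(seed)
    y = 8.0 + emax / (1 + 10 ** (slope * (ec50 - design.x))) \
        + rng.normal(0, sd, design.n)
    return fit_gam(design, y)


class TestClassifyDirection:
    @pytest.mark.parametrize("y0,ymax,ymin,expected", [
        (10.0, 10.2, 9.0, "inhibitor"),
        (10.0, 12.0, 9.5, "activator"),
        (10.0, 10.0, 10.0, "inhibitor"),   # exact tie -> inhibitor
    ])
    def test_examples(self, y0, ymax, ymin, expected):
        assert classify_direction(y0, ymin, ymax) == expected

    @given(st.floats(-5, 5), st.floats(0, 3), st.floats(0, 3),
           st.floats(-100, 100))
    @settings(deadline=None, max_examples=80)
    def test_shift_invariance(self, y0, rise, drop, shift):
        assume(abs(rise - drop) > 1e-6)  # float shifts can flip exact ties
        a = classify_direction(y0, y0 - drop, y0 + rise)
        b = classify_direction(y0 + shift, y0 - drop + shift,
                               y0 + rise + shift)
        assert a == b


class TestFormulaIdentities:
    @pytest.mark.parametrize("log2imax,expected", [(-1.0, 0.5), (0.0, 0.0),
                                                   (-2.0, 0.75)])
    def test_percent_max_inhibition(self, log2imax, expected):
        assert percent_max_inhibition(log2imax) == pytest.approx(expected)

    def test_percent_max_inhibition_domain(self):
        with pytest.raises(ValueError):
            percent_max_inhibition(0.3)

    def test_xc50_linear(self):
        assert xc50_linear(-4.0, -4.0) == pytest.approx(1.0)
        assert xc50_linear(-2.0, -4.0) == pytest.approx(100.0)
        # round trip
        assert np.log10(xc50_linear(-2.7, -4.0)) + (-4.0) == pytest.approx(-2.7)


class TestFittedExtrema:
    def test_monotone_curve_extremum_at_boundary(self, design):
        # near-noiseless gentle sigmoid: the fitted curve stays monotone
        fit = _sigmoid_fit(design, seed=1, slope=0.8, sd=0.002)
        grid = np.linspace(design.cp, design.x_max, 200)
        assert np.all(np.diff(fit.curve(grid, check_range=False)) <= 1e-9)
        y0, ymin, ymax, x_at_min, x_at_max = fitted_extrema(fit, cp=design.cp)
        assert x_at_min == pytest.approx(design.x_max)
        assert ymin < y0

    def test_flat_curve(self, design):
        rng = np.random.default_rng(2)
        fit = fit_gam(design, rng.normal(8, 0.05, design.n),
                      log10_lambda_bounds=(12.0, 12.0))
        y0, ymin, ymax, *_ = fitted_extrema(fit, cp=design.cp)
        # heavy smoothing leaves only the (nearly flat) linear trend
        assert ymax - ymin < 0.1
        assert min(ymin, y0) <= y0 <= max(ymax, y0)

    def test_interior_extremum_near_parabola_vertex(self, design):
        # noiseless parabola with vertex at x = -1
        y = 8.0 - 0.5 * (design.x + 1.0) ** 2
        fit = fit_gam(design, y + np.random.default_rng(3).normal(
            0, 1e-4, design.n))
        *_, x_at_max = fitted_extrema(fit, cp=design.cp)
        assert x_at_max == pytest.approx(-1.0, abs=0.05)


class TestXC50:
    def test_linear_curve_midpoint_at_center(self, design):
        rng = np.random.default_rng(4)
        y = 8.0 - 0.5 * design.x + rng.normal(0, 0.01, design.n)
        fit = fit_gam(design, y, log10_lambda_bounds=(12.0, 12.0))
        x50 = xc50(fit, design.x_max, cp=design.cp)
        assert x50 == pytest.approx((design.cp + design.x_max) / 2, abs=1e-3)

    def test_hill_curve_recovery(self, design):
        fit = _sigmoid_fit(design, seed=5, emax=-2.0, ec50=-1.0, slope=1.0,
                           sd=0.02)
        est = estimate_potency(fit, cp=design.cp)
        assert est.log10_xc50 == pytest.approx(-1.0, abs=0.1)

    def test_midpoint_identity(self, design):
        for seed in range(5):
            fit = _sigmoid_fit(design, seed=seed, emax=-1.0 - 0.3 * seed)
            est = estimate_potency(fit, cp=design.cp)
            if not np.isfinite(est.log10_xc50):
                continue
            f_at = float(fit.curve(np.array([est.log10_xc50]),
                                   check_range=False)[0])
            assert abs(f_at - 0.5 * (est.y0 + est.y_ext)) < 1e-6

    def test_non_monotone_smallest_crossing(self, design):
        # rise-then-fall: midpoint crossed twice; smaller x must be returned
        y = 8.0 + 2.0 * np.exp(-0.5 * ((design.x + 1.0) / 0.8) ** 2)
        fit = fit_gam(design, y + np.random.default_rng(6).normal(
            0, 1e-3, design.n))
        est = estimate_potency(fit, cp=design.cp)
        assert est.direction == "activator"
        assert est.log10_xc50 < est.x_ext
        # verify it is the first crossing: no earlier sign change
        grid = np.linspace(design.cp, est.log10_xc50 - 1e-4, 200)
        target = 0.5 * (est.y0 + est.y_ext)
        vals = fit.curve(grid, check_range=False) - target
        assert np.all(np.sign(vals) == np.sign(vals[0]))

    def test_flat_fit_yields_nan(self, design):
        y = np.full(design.n, 8.0)
        fit = fit_gam(design, y + np.random.default_rng(7).normal(
            0, 1e-9, design.n), log10_lambda_bounds=(12.0, 12.0))
        est = estimate_potency(fit, cp=design.cp)
        assert "flat_curve_no_xc50" in est.flags or np.isfinite(est.log10_xc50)


class TestMaxEffect:
    def test_inhibitor_effect_recovered(self, design):
        errs = []
        for seed in range(20):
            spec = well_conditioned_spec(3000 + seed)
            sim = simulate_experiment(spec)
            d = sim.experiment.design()
            fit = fit_gam(d, sim.experiment.y(sim.experiment.gene_ids[0]))
            est = estimate_potency(fit, cp=d.cp)
            errs.append(abs(est.log2_max_effect
                            - sim.truth.true_max_effect.iloc[0]))
        assert np.median(errs) < 0.3

    def test_se_positive_for_noisy_fit(self, design):
        fit = _sigmoid_fit(design, seed=8)
        _, _, _, _, x_at_max = fitted_extrema(fit, cp=design.cp)
        eff, se = max_effect_with_se(fit, design.x_max, cp=design.cp)
        assert se > 0


class TestDeltaSE:
    def _fd_gradient(self, fit, x50, x_ext, cp, h=1e-6):
        """Finite-difference d x50 / d beta with x_ext held fixed."""
        base_coef = fit.coef_.copy()
        J = fit.basis_.J

        def solve_x50(coef):
            beta = coef[:J]
            b = fit.basis_.evaluate
            target = 0.5 * (float(b(cp)[0] @ beta)
                            + float(b(x_ext)[0] @ beta))

            def g(x):
                return float(b(x)[0] @ beta) - target
            lo = max(cp + 1e-9, x50 - 0.2)
            hi = min(x_ext, x50 + 0.2)
            return optimize.brentq(g, lo, hi, xtol=1e-12)

        grad = np.zeros_like(base_coef)
        for j in range(base_coef.size):
            for sgn in (+1, -1):
                coef = base_coef.copy()
                coef[j] += sgn * h
                grad[j] += sgn * solve_x50(coef)
        return grad / (2 * h)

    def test_gradient_matches_finite_differences(self, design):
        for seed in range(8):
            fit = _sigmoid_fit(design, seed=seed, emax=-1.8,
                               ec50=-1.2 + 0.1 * seed)
            est = estimate_potency(fit, cp=design.cp)
            if not np.isfinite(est.log10_xc50):
                continue
            fprime = float(fit.curve_deriv(np.array([est.log10_xc50]))[0])
            g = (0.5 * (fit.basis_row(design.cp) + fit.basis_row(est.x_ext))
                 - fit.basis_row(est.log10_xc50)) / fprime
            fd = self._fd_gradient(fit, est.log10_xc50, est.x_ext, design.cp)
            np.testing.assert_allclose(g, fd, rtol=1e-3, atol=1e-9)

    def test_steeper_curve_shrinks_se(self, design):
        fit = _sigmoid_fit(design, seed=9, emax=-1.5)
        est = estimate_potency(fit, cp=design.cp)
        se1 = est.se_xc50
        # doubling all coefficients doubles the slope at the (unchanged)
        # midpoint crossing while V is held fixed
        fit.coef_ = fit.coef_ * 2.0
        est2 = estimate_potency(fit, cp=design.cp)
        assert est2.log10_xc50 == pytest.approx(est.log10_xc50, abs=1e-6)
        assert est2.se_xc50 < se1
        assert est2.se_xc50 == pytest.approx(se1 / 2, rel=1e-3)

    def test_rlm_fit_rejected(self, design):
        rng = np.random.default_rng(10)
        rlm = fit_rlm(design, rng.normal(8, 0.1, design.n))
        with pytest.raises(TypeError):
            estimate_potency(rlm, cp=design.cp)


class TestBootstrap:
    def test_deterministic_under_seed(self, design):
        fit_y = 8.0 - 1.5 / (1 + 10 ** (1.0 * (-1.0 - design.x)))
        y = fit_y + np.random.default_rng(11).normal(0, 0.1, design.n)
        se1, f1 = bootstrap_se_xc50(design, y, R=120, seed=99)
        se2, f2 = bootstrap_se_xc50(design, y, R=120, seed=99)
        assert se1 == se2 and f1 == f2

    def test_minimum_resamples_enforced(self, design):
        with pytest.raises(ValueError):
            bootstrap_se_xc50(design, np.zeros(design.n), R=50, seed=0)

    def test_agrees_with_delta_method(self, design):
        sim = simulate_experiment(well_conditioned_spec(777))
        d = sim.experiment.design()
        y = sim.experiment.y(sim.experiment.gene_ids[0])
        fit = fit_gam(d, y)
        est = estimate_potency(fit, cp=d.cp)
        bse, _ = bootstrap_se_xc50(d, y, R=500, seed=1)
        assert est.se_xc50 == pytest.approx(bse, rel=0.5)


def test_run_potency_table(sigmoid_experiment):
    from dosecurve.pipeline import fit_experiment

    fits, _ = fit_experiment(sigmoid_experiment)
    table = run_potency(sigmoid_experiment, fits)
    assert set(table["direction"]) <= {"activator", "inhibitor"}
    assert len(table) == len(sigmoid_experiment.gene_ids)
    ok = np.isfinite(table["log10_xc50"])
    assert np.all(table.loc[ok, "log10_xc50"] > table.loc[ok, "cp"])
    assert np.all(table.loc[ok, "log10_xc50"] <= table.loc[ok, "x_ext"] + 1e-9)
    act = table["direction"] == "activator"
    assert np.all(table.loc[act, "log2_max_effect"] >= 0)
    assert np.all(table.loc[~act, "log2_max_effect"] <= 0)
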