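import subprocess
import textwrap

import numpy as np
import pytest
from sklearn.base import clone

from dosecurve.design import transform_doses
from dosecurve.models import (FitError, HuberANOVA, OLSANOVA,
                              PenalizedSplineGAM, fit_gam, fit_lm, fit_rlm,
                              predict_with_se, select_model_kind)


@pytest.fixture(scope="module")
def design():
    doses = np.repeat(10.0 / (10 ** 0.5) ** np.arange(8)[::-1], 3)
    return transform_doses(np.concatenate([[0.0] * 6, doses]))


class TestPenalizedSplineGAM:
    def test_recovers_straight_line(self, design):
        rng = np.random.default_rng(0)
        y = 2.0 + 0.5 * design.x + rng.normal(0, 0.01, design.n)
        fit = fit_gam(design, y)
        grid = np.linspace(design.cp, design.x_max, 50)
        assert np.max(np.abs(fit.curve(grid) - (2.0 + 0.5 * grid))) < 0.05

    def test_infinite_smoothing_gives_ols_line(self, design):
        rng = np.random.default_rng(1)
        y = 1.0 - 0.3 * design.x + rng.normal(0, 0.2, design.n)
        fit = fit_gam(design, y, log10_lambda_bounds=(12.0, 12.0))
        assert fit.edf_ == pytest.approx(2.0, abs=1e-3)
        slope, icept = np.polyfit(design.x, y, 1)
        grid = np.linspace(design.cp, design.x_max, 20)
        np.testing.assert_allclose(fit.curve(grid), icept + slope * grid,
                                   atol=1e-4)

    def test_two_time_levels_share_basis_symmetrically(self):
        doses = np.tile(np.repeat([0.0, 0.01, 0.1, 1.0, 3.0, 10.0, 0.03,
                                   0.3, 3e-3], 3), 2)
        times = np.repeat([6, 24], doses.size // 2)
        design = transform_doses(doses, time_labels=times)
        rng = np.random.default_rng(3)
        y_half = rng.normal(8.0, 0.1, doses.size // 2)
        y = np.concatenate([y_half, y_half])  # identical data in both levels
        fit = fit_gam(design, y)
        J = fit.basis_.J
        np.testing.assert_allclose(fit.coef_[:J], fit.coef_[J:2 * J],
                                   atol=1e-6)

    def test_extrapolation_refused(self, design):
        rng = np.random.default_rng(4)
        fit = fit_gam(design, rng.normal(8, 0.1, design.n))
        with pytest.raises(ValueError, match="extrapolate"):
            fit.predict(np.array([[design.x_max + 1.0, 0.0]]))

    def test_edf_monotone_in_lambda(self, design):
        rng = np.random.default_rng(5)
        y = rng.normal(8, 0.3, design.n)
        edfs = [fit_gam(design, y, log10_lambda_bounds=(rho, rho)).edf_
                for rho in (-6.0, -2.0, 0.0, 2.0, 6.0)]
        assert all(a >= b - 1e-9 for a, b in zip(edfs, edfs[1:]))
        for rho in (-6.0, 2.0):
            fit = fit_gam(design, y, log10_lambda_bounds=(rho, rho))
            assert fit.df_resid_ + fit.edf_ == pytest.approx(design.n)

    def test_sklearn_protocol(self, design):
        est = PenalizedSplineGAM(basis_dim=4)
        params = est.get_params()
        assert params["basis_dim"] == 4
        cloned = clone(est)
        rng = np.random.default_rng(6)
        X = design.design_matrix_input()
        y = rng.normal(8, 0.1, design.n)
        cloned.fit(X, y)
        assert cloned.predict(X).shape == y.shape
        assert np.all(cloned.predict_se(X) >= 0)


class TestAgainstReferenceGAMToolchain:
    """Cross-check penalized-spline fits against R mgcv on identical data."""

    def test_contrast_estimates_and_ses_match_mgcv(self, design, tmp_path):
        rng = np.random.default_rng(11)
        n_genes = 6
        Y = np.stack([
            8.0 - 1.5 / (1 + 10 ** (1.0 * (-1.0 - design.x)))
            + rng.normal(0, 0.1, design.n) for _ in range(n_genes)])
        np.savetxt(tmp_path / "x.txt", design.x)
        np.savetxt(tmp_path / "y.txt", Y)
        np.savetxt(tmp_path / "q.txt", np.log10(design.dose_levels))
        r_code = textwrap.dedent(f"""
            suppressMessages(library(mgcv))
            x <- scan('{tmp_path}/x.txt', quiet=TRUE)
            Y <- as.matrix(read.table('{tmp_path}/y.txt'))
            xs <- scan('{tmp_path}/q.txt', quiet=TRUE)
            cp <- min(x)
            out <- NULL
            for (g in 1:nrow(Y)) {{
              fit <- gam(Y[g,] ~ s(x, k=4), method="GCV.Cp")
              Xq <- predict(fit, newdata=data.frame(x=c(cp, xs)),
                            type="lpmatrix")
              C <- sweep(Xq[-1,,drop=FALSE], 2, Xq[1,])
              est <- C %*% coef(fit)
              se <- sqrt(rowSums((C %*% fit$Vp) * C))
              out <- rbind(out, cbind(g, xs, est, se))
            }}
            write.table(out, '{tmp_path}/mgcv.txt', row.names=FALSE,
                        col.names=FALSE)
        """)
        subprocess.run(["Rscript", "-e", r_code], check=True,
                       capture_output=True)
        ref = np.loadtxt(tmp_path / "mgcv.txt")

        from dosecurve.diffexpr import contrast_vs_vehicle
        ratios, diffs = [], []
        for g in range(n_genes):
            fit = fit_gam(design, Y[g])
            for dose in design.dose_levels:
                xq = float(np.log10(dose))
                fc, se = contrast_vs_vehicle(fit, xq, 0)
                row = ref[(ref[:, 0] == g + 1)
                          & (np.abs(ref[:, 1] - xq) < 1e-9)][0]
                diffs.append(abs(fc - row[2]))
                ratios.append(se / row[3])
        # smoothing parameters are optimized by different algorithms, so
        # agreement is close but not bitwise
        assert np.median(np.abs(np.array(ratios) - 1)) < 0.02
        assert np.max(diffs) < 0.05


class TestCellMeansModels:
    def _design(self, values_by_cell):
        doses, y = [], []
        for dose, vals in values_by_cell.items():
            doses.extend([dose] * len(vals))
            y.extend(vals)
        return transform_doses(np.array(doses)), np.array(y)

    def test_rlm_equals_ols_on_clean_data(self):
        design, y = self._design({0.0: (5.0, 5.1, 4.9),
                                  1.0: (4.0, 4.1, 3.9)})
        rlm = fit_rlm(design, y)
        lm = fit_lm(design, y)
        np.testing.assert_allclose(rlm.coef_, [5.0, 4.0], atol=1e-6)
        np.testing.assert_allclose(rlm.coef_, lm.coef_, atol=1e-6)

    def test_huber_downweights_gross_outlier(self):
        design, y = self._design({0.0: (5.0, 5.1, 4.9, 5.05, 4.95, 15.0),
                                  1.0: (4.0, 4.1, 3.9, 4.05, 3.95, 4.02)})
        rlm = fit_rlm(design, y)
        naive_mean = np.mean([5.0, 5.1, 4.9, 5.05, 4.95, 15.0])
        assert abs(rlm.coef_[0] - 5.0) < abs(naive_mean - 5.0)

    def test_no_residual_df_rejected(self):
        design, y = self._design({0.0: (5.0,), 1.0: (4.0,)})
        with pytest.raises(FitError):
            fit_rlm(design, y)

    def test_two_way_cell_means(self):
        design = transform_doses([0, 0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 1],
                                 time_labels=[6] * 6 + [24] * 6)
        rng = np.random.default_rng(8)
        y = rng.normal(8, 0.1, 12)
        rlm = fit_rlm(design, y)
        assert rlm.coef_.size == 4

    def test_degenerate_identical_replicates(self):
        design, y = self._design({0.0: (5.0, 5.0, 5.0), 1.0: (4.0, 4.0, 4.0)})
        rlm = fit_rlm(design, y)
        assert rlm.degenerate_
        np.testing.assert_array_equal(rlm.coef_, [5.0, 4.0])
        assert np.all(rlm.cov_ == 0)

    def test_ols_variances_closed_form(self):
        design, y = self._design({0.0: (5.0, 5.4, 4.6), 1.0: (4.1, 3.9, 4.0)})
        lm = fit_lm(design, y)
        sigma2 = np.sum((y - lm.coef_[[0, 0, 0, 1, 1, 1]]) ** 2) / 4
        np.testing.assert_allclose(np.diag(lm.cov_), sigma2 / 3, rtol=1e-10)

    def test_query_outside_design_points(self):
        design, y = self._design({0.0: (5.0, 5.1, 4.9), 1.0: (4.0, 4.1, 3.9)})
        rlm = fit_rlm(design, y)
        with pytest.raises(ValueError, match="design"):
            predict_with_se(rlm, 0.5, 0)


class TestModelGate:
    @pytest.mark.parametrize("C,expected", [(5, "GAM"), (6, "GAM"),
                                            (4, "RLM"), (3, "RLM"),
                                            (1, "RLM")])
    def test_gate(self, C, expected):
        assert select_model_kind(C) == expected

    def test_zero_concentrations_invalid(self):
        with pytest.raises(ValueError):
            select_model_kind(0)


def test_families_agree_on_clean_linear_data(design):
    """In the heavy-smoothing / no-outlier limits all three fits coincide."""
    rng = np.random.default_rng(9)
    y = 7.0 + 0.2 * design.x + rng.normal(0, 0.05, design.n)
    gam = fit_gam(design, y, log10_lambda_bounds=(12.0, 12.0))
    rlm = fit_rlm(design, y)
    lm = fit_lm(design, y)
    np.testing.assert_allclose(rlm.coef_, lm.coef_, atol=0.02)
    for dose in design.dose_levels:
        xq = float(np.log10(dose))
        yg, _ = predict_with_se(gam, xq, 0)
        yl, _ = predict_with_se(lm, xq, 0)
        assert abs(yg - yl) < 0.06
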