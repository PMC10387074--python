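import numpy as np
import pandas as pd
import pytest
from scipy import stats

from iadfnet.zaga_gam import (
    GamSpec,
    ModelTable,
    bspline_basis,
    cvm_test,
    effect_summary,
    fit_zaga_gam,
    quantile_residuals,
)


class TestBsplineBasis:
    def test_partition_of_unity(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(3, 17, 200)
        B, P, _ = bspline_basis(x, n_knots=12)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_second_difference_penalty_annihilates_linear(self):
        x = np.linspace(0, 1, 50)
        B, P, basis = bspline_basis(x, n_knots=10, penalty_order=2)
        # coefficients of an exactly linear function: for B-splines the Greville
        # abscissae map linear coefficient sequences to linear functions
        t, d = basis.knots, basis.degree
        greville = np.array([t[i + 1 : i + d + 1].mean() for i in range(basis.n_funcs)])
        coef = 2.0 + 3.0 * greville
        D = np.diff(np.eye(basis.n_funcs), n=2, axis=0)
        assert np.abs(D @ coef).max() == pytest.approx(0.0, abs=1e-12)
        assert coef @ P @ coef == pytest.approx(0.0, abs=1e-12)
        # and the basis reproduces the linear function itself
        np.testing.assert_allclose(B @ coef, 2.0 + 3.0 * x, atol=1e-10)

    def test_no_silent_extrapolation(self):
        B, P, basis = bspline_basis(np.linspace(0, 1, 30))
        with pytest.raises(ValueError, match="span"):
            basis.design(np.array([1.5]))

    def test_zero_lambda_matches_normal_equations(self):
        """Penalized fit at lambda -> 0 equals the unpenalized least-squares
        solution computed directly from the normal equations."""
        rng = np.random.default_rng(4)
        x = np.sort(rng.uniform(0, 10, 300))
        y = np.sin(x) + rng.normal(0, 0.1, len(x))
        B, P, _ = bspline_basis(x, n_knots=8)
        lam = 1e-12
        beta_pen = np.linalg.solve(B.T @ B + lam * P, B.T @ y)
        beta_ls, *_ = np.linalg.lstsq(B, y, rcond=None)
        np.testing.assert_allclose(B @ beta_pen, B @ beta_ls, atol=1e-8)

    def test_knot_count_validated(self):
        with pytest.raises(ValueError):
            bspline_basis(np.linspace(0, 1, 30), n_knots=4, degree=3)


class TestFitZagaGam:
    def test_reduces_to_gamma_glm(self):
        """With no smooths, no zeros and tiny dispersion, estimates match an
        independent IRLS gamma GLM (statsmodels) to 1e-6."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        n = 400
        alt = rng.uniform(0, 1000, n)
        tp = rng.normal(800, 150, n)
        temp = rng.normal(10, 3, n)
        spei = rng.normal(0, 1, n)
        species = rng.choice(["AA", "BB"], n)
        cluster = rng.choice(["c1", "c2"], n)
        eta = (
            0.5 - 3e-4 * (alt - alt.mean()) + 2e-4 * (tp - tp.mean())
            + 0.05 * (temp - temp.mean()) + 0.1 * (spei - spei.mean())
            + 0.2 * (species == "BB") - 0.3 * (cluster == "c2")
        )
        sigma = 0.05
        y = rng.gamma(1 / sigma**2, np.exp(eta) * sigma**2)
        tab = pd.DataFrame(
            dict(site_id="x", species=species, cluster=cluster, year=2000,
                 response=y, alt=alt, lat=35.0, rw=100.0, tp=tp, temp=temp,
                 spei=spei, weight=1.0)
        )
        with pytest.warns(UserWarning, match="nu fixed at 0"):
            fit = fit_zaga_gam(tab, GamSpec(smooth=()))
        X = pd.DataFrame(
            dict(alt=alt - alt.mean(), BB=(species == "BB").astype(float),
                 tp=tp - tp.mean(), tpBB=(tp - tp.mean()) * (species == "BB"),
                 temp=temp - temp.mean(), tempBB=(temp - temp.mean()) * (species == "BB"),
                 spei=spei - spei.mean(), speiBB=(spei - spei.mean()) * (species == "BB"),
                 c2=(cluster == "c2").astype(float))
        )
        oracle = sm.GLM(
            y, sm.add_constant(X), family=sm.families.Gamma(sm.families.links.Log())
        ).fit(tol=1e-12)
        np.testing.assert_allclose(
            fit.coef["estimate"].to_numpy(), oracle.params.to_numpy(), atol=1e-6
        )

    def test_row_permutation_invariance(self, zaga_simulator):
        table, _ = zaga_simulator(1, n=600)
        fit1 = fit_zaga_gam(table)
        perm = table.sample(frac=1.0, random_state=9).reset_index(drop=True)
        fit2 = fit_zaga_gam(perm)
        np.testing.assert_allclose(
            fit1.coef["estimate"], fit2.coef["estimate"], rtol=1e-8
        )
        assert fit1.nu == pytest.approx(fit2.nu)

    def test_coefficient_recovery_single_fit(self, zaga_simulator):
        table, true = zaga_simulator(42)
        fit = fit_zaga_gam(table)
        assert fit.converged
        est = fit.coef.set_index("name")
        for name, val in true.items():
            row = est.loc[name]
            assert abs(row["estimate"] - val) < 4 * row["se"], name

    def test_rw_scale_equivariance(self, zaga_simulator):
        """Scaling ring width rescales its spline's knots but leaves fitted
        values essentially unchanged."""
        table, _ = zaga_simulator(5, n=800)
        fit1 = fit_zaga_gam(table)
        scaled = table.copy()
        scaled["rw"] = scaled["rw"] * 10.0
        fit2 = fit_zaga_gam(scaled)
        np.testing.assert_allclose(fit1.predict_mu(), fit2.predict_mu(), rtol=1e-3)

    def test_detrended_response_rejected(self, zaga_simulator):
        table, _ = zaga_simulator(2, n=200)
        table.loc[0, "response"] = -0.1
        with pytest.raises(ValueError, match="ZAGA response"):
            ModelTable(table)

    def test_all_zero_response_rejected(self, zaga_simulator):
        table, _ = zaga_simulator(2, n=200)
        table["response"] = 0.0
        with pytest.raises(ValueError, match="zero"):
            fit_zaga_gam(table)

    def test_aliased_species_cluster_dropped_with_report(self, zaga_simulator):
        table, _ = zaga_simulator(6, n=800)
        # nest species entirely within cluster: AA->c1, BB->c2
        table["cluster"] = np.where(table["species"] == "AA", "c1", "c2")
        with pytest.warns(UserWarning, match="aliased"):
            fit = fit_zaga_gam(table)
        assert fit.dropped_columns
        assert fit.converged

    def test_r_squared_zero_for_constant_fit(self, zaga_simulator):
        table, _ = zaga_simulator(7, n=300)
        spec = GamSpec(linear=(), smooth=(), climate_vars=())
        single = table.copy()
        single["species"] = "AA"
        single["cluster"] = "c1"
        fit = fit_zaga_gam(single, spec)
        assert fit.r_squared == 0.0


class TestEffectSummary:
    def test_signs_match_generator(self, zaga_simulator):
        table, _ = zaga_simulator(11)
        fit = fit_zaga_gam(table)
        summ = effect_summary(fit).set_index(["species", "variable"])
        # species AA has positive tp/temp/spei slopes; BB's temp slope is 0
        assert summ.loc[("AA", "temp"), "sign"] == "+"
        assert summ.loc[("AA", "spei"), "sign"] == "+"
        assert summ.loc[("BB", "tp"), "sign"] == "-"

    def test_null_slope_ns(self, zaga_simulator):
        table, _ = zaga_simulator(13, temp_slope_b=-0.08)
        fit = fit_zaga_gam(table)
        summ = effect_summary(fit).set_index(["species", "variable"])
        est = summ.loc[("BB", "temp")]
        # true species-B temperature slope is 0.08 - 0.08 = 0
        assert abs(est["estimate"]) < 3 * est["se"]


class TestQuantileResiduals:
    def test_seeded_determinism(self, zaga_simulator):
        table, _ = zaga_simulator(3, n=500)
        fit = fit_zaga_gam(table)
        np.testing.assert_array_equal(
            quantile_residuals(fit, 7), quantile_residuals(fit, 7)
        )
        assert not np.array_equal(
            quantile_residuals(fit, 7), quantile_residuals(fit, 8)
        )

    def test_median_positive_observation_maps_to_zero(self, zaga_simulator):
        """An observation at the fitted ZAGA median (CDF 1/2) has residual 0."""
        table, _ = zaga_simulator(4, n=500)
        fit = fit_zaga_gam(table)
        mu = fit.predict_mu()
        shape = 1.0 / fit.sigma**2
        i = int(np.flatnonzero(table["response"] > 0)[0])
        target_u = (0.5 - fit.nu) / (1.0 - fit.nu)
        y_med = stats.gamma.ppf(target_u, a=shape, scale=mu[i] * fit.sigma**2)
        fit.table.loc[i, "response"] = y_med
        res = quantile_residuals(fit, 0)
        assert res[i] == pytest.approx(0.0, abs=1e-10)

    def test_normality_of_correct_model(self, zaga_simulator):
        table, _ = zaga_simulator(19, n=800)
        fit = fit_zaga_gam(table)
        w2, p = cvm_test(quantile_residuals(fit, 19))
        assert p > 0.05


class TestCvm:
    # frozen oracle values from R nortest::cvm.test on the same inputs
    HAND10 = [0.3, -1.2, 2.5, 0.1, -0.4, 1.7, -2.2, 0.9, -0.6, 0.05]
    HAND12 = [1.1, 2.3, 0.4, 5.6, 3.2, 2.2, 1.9, 0.1, 4.4, 2.8, 3.3, 1.5]

    def test_statistic_matches_independent_formula(self):
        """W2 recomputed from the definition, term by term, to 1e-10."""
        x = np.sort(np.array(self.HAND10))
        n = len(x)
        z = (x - x.mean()) / x.std(ddof=1)
        w2_direct = 1.0 / (12 * n) + sum(
            (stats.norm.cdf(z[i]) - (2 * (i + 1) - 1) / (2 * n)) ** 2 for i in range(n)
        )
        w2, _ = cvm_test(self.HAND10)
        assert w2 == pytest.approx(w2_direct, abs=1e-10)

    @pytest.mark.parametrize(
        "data,expected_w,expected_p",
        [
            (HAND10, 0.0262041578608563, 0.878767042669854),
            (HAND12, 0.0207517617973924, 0.952652779357606),
        ],
    )
    def test_matches_r_nortest(self, data, expected_w, expected_p):
        w2, p = cvm_test(data)
        assert w2 == pytest.approx(expected_w, abs=1e-12)
        assert p == pytest.approx(expected_p, abs=1e-9)

    def test_normal_accepted_exponential_rejected(self):
        rng = np.random.default_rng(123)
        accepted = sum(
            cvm_test(rng.normal(size=500))[1] > 0.05 for _ in range(20)
        )
        assert accepted >= 15
        rejected = sum(cvm_test(rng.exponential(size=500))[1] < 0.01 for _ in range(20))
        assert rejected == 20

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            cvm_test(np.ones(20))
        with pytest.raises(ValueError):
            cvm_test([1.0, 2.0])
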