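"""Collinearity screening, VIF diagnostics, and OLS driver fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import urbanesv as u
from urbanesv import drivers as drv
from urbanesv.synthetic import SyntheticConfig, gen_driver_panel


@pytest.fixture(scope="module")
def synth_panel():
    return gen_driver_panel(SyntheticConfig(seed=7))


class TestPearsonScreen:
    def test_identical_pair_drops_exactly_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        df = pd.DataFrame({"X1": x, "X2": x, "X3": rng.normal(size=30)})
        res = drv.pearson_screen(df, ["X1", "X2", "X3"])
        assert len(res.kept) == 2 and "X3" in res.kept
        assert len(res.dropped) == 1 and res.dropped[0][1] == "pairwise_r"
        assert res.dropped[0][0] == "X2"  # tie broken by column order, X1 kept

    def test_exact_linear_combination_survives_pairwise_stage(self):
        # x3 = x1 + x2 with pairwise |r| < 0.75: pairwise screening is blind to it
        rng = np.random.default_rng(1)
        x1, x2 = rng.normal(size=200), rng.normal(size=200)
        df = pd.DataFrame({"X1": x1, "X2": x2, "X3": x1 + x2})
        corr = df.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() < 0.75
        res = drv.pearson_screen(df, ["X1", "X2", "X3"])
        assert res.kept == ["X1", "X2", "X3"]

    def test_engineered_panel_keeps_one_per_block(self, synth_panel):
        panel, truth = synth_panel
        candidates = [f"X{i}" for i in range(1, 20)]
        res = drv.pearson_screen(panel, candidates, threshold=0.75)
        assert len(res.kept) == 7
        assert len(res.dropped) == 12
        corr = panel[res.kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() < 0.75  # brute-force check of all kept pairs

    def test_idempotent(self, synth_panel):
        panel, _ = synth_panel
        first = drv.pearson_screen(panel, [f"X{i}" for i in range(1, 20)])
        second = drv.pearson_screen(panel, first.kept)
        assert second.kept == first.kept and not second.dropped

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"X1": [1.0] * 10, "X2": np.arange(10.0)})
        with pytest.raises(ValueError, match="X1"):
            drv.pearson_screen(df, ["X1", "X2"])


class TestVIF:
    def test_orthogonal_predictors_give_one(self):
        n = 64
        t = np.arange(n)
        df = pd.DataFrame({
            "X1": np.where(t % 2 == 0, 1.0, -1.0),
            "X2": np.where((t // 2) % 2 == 0, 1.0, -1.0),
            "X3": np.where((t // 4) % 2 == 0, 1.0, -1.0),
        })
        v = drv.vif(df, ["X1", "X2", "X3"])
        assert np.allclose(v, 1.0)

    def test_near_collinear_exceeds_100(self):
        rng = np.random.default_rng(3)
        x1, x2 = rng.normal(size=100), rng.normal(size=100)
        df = pd.DataFrame({"X1": x1, "X2": x2,
                           "X3": x1 + x2 + rng.normal(0, 0.01, size=100)})
        assert drv.vif(df, ["X1", "X2", "X3"])["X3"] > 100

    def test_perfect_collinearity_is_inf_not_exception(self):
        rng = np.random.default_rng(4)
        x1, x2 = rng.normal(size=50), rng.normal(size=50)
        df = pd.DataFrame({"X1": x1, "X2": x2, "X3": x1 + x2})
        assert np.isinf(drv.vif(df, ["X1", "X2", "X3"])["X3"])

    def test_screened_synthetic_panel_passes_threshold(self, synth_panel):
        panel, _ = synth_panel
        kept = drv.pearson_screen(panel, [f"X{i}" for i in range(1, 20)]).kept
        assert (drv.vif(panel, kept) < 5).all()


class TestOLS:
    def test_noiseless_line_recovered_exactly(self):
        x = np.linspace(0, 10, 20)
        df = pd.DataFrame({"X1": x, "Y": 2.0 + 3.0 * x})
        fit = drv.fit_ols(df, "Y", ["X1"])
        assert fit.intercept == pytest.approx(2.0)
        assert fit.coefficients["X1"] == pytest.approx(3.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_fitted_plus_residuals_reproduce_response(self, synth_panel):
        panel, _ = synth_panel
        kept = drv.pearson_screen(panel, [f"X{i}" for i in range(1, 20)]).kept
        fit = drv.fit_ols(panel, "Y", kept)
        assert np.allclose(fit.fitted + fit.residuals, panel["Y"])
        assert 0.0 <= fit.r_squared <= 1.0

    def test_singular_design_errors(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        df = pd.DataFrame({"X1": x, "X2": 2 * x, "Y": rng.normal(size=20)})
        with pytest.raises(ValueError, match="singular"):
            drv.fit_ols(df, "Y", ["X1", "X2"])

    def test_stars_thresholds(self):
        assert drv._stars(0.005) == "***"
        assert drv._stars(0.03) == "**"
        assert drv._stars(0.08) == "*"
        assert drv._stars(0.2) == ""

    def test_ci_coverage_of_known_coefficients(self):
        """Estimates fall inside their own 95% CIs of the truth in >= 90% of
        200 seeded replicates (exact coverage would be 95% per coefficient)."""
        hits, trials = 0, 0
        for seed in range(200):
            panel, truth = gen_driver_panel(SyntheticConfig(seed=seed))
            fit = drv.fit_ols(panel, "Y", list(truth.alpha))
            res_df = fit.n - len(truth.alpha) - 1
            tcrit = stats.t.ppf(0.975, res_df)
            X = np.column_stack([np.ones(fit.n)] + [panel[v] for v in truth.alpha])
            sigma2 = (fit.residuals**2).sum() / res_df
            cov = sigma2 * np.linalg.inv(X.T @ X)
            ses = np.sqrt(np.diag(cov))[1:]
            for (var, alpha_true), se in zip(truth.alpha.items(), ses):
                est = fit.coefficients[var]
                hits += abs(est - alpha_true) <= tcrit * se
                trials += 1
        assert hits / trials >= 0.90

    def test_type_one_error_calibrated(self):
        """Pure-noise responses reject each coefficient at the 5% level about
        5% of the time over 200 seeded replicates."""
        rng = np.random.default_rng(11)
        rejections, trials = 0, 0
        for _ in range(200):
            X = pd.DataFrame(rng.normal(size=(78, 5)), columns=[f"X{i}" for i in range(1, 6)])
            X["Y"] = rng.normal(size=78)
            fit = drv.fit_ols(X, "Y", [f"X{i}" for i in range(1, 6)])
            rejections += int((fit.pvalues <= 0.05).sum())
            trials += 5
        assert 0.02 <= rejections / trials <= 0.08


class TestPipelineAndEstimator:
    def test_pipeline_n_is_78(self, synth_panel):
        panel, _ = synth_panel
        report = drv.driver_pipeline(panel)
        assert all(fit.n == 78 for fit in report.fits.values())
        assert set(report.table.columns) == {"Y", "Y1", "Y2", "Y3", "Y4"}
        assert report.table.loc["N", "Y"] == "78"

    def test_identical_responses_identical_fits(self, synth_panel):
        panel, _ = synth_panel
        clone = panel.copy()
        for r in ("Y1", "Y2"):
            clone[r] = clone["Y"]
        report = drv.driver_pipeline(clone, responses=["Y", "Y1", "Y2"])
        assert np.allclose(report.fits["Y"].coefficients, report.fits["Y1"].coefficients)
        assert np.allclose(report.fits["Y"].coefficients, report.fits["Y2"].coefficients)

    def test_truth_sign_pattern_recovered(self, synth_panel):
        panel, truth = synth_panel
        report = drv.driver_pipeline(panel, responses=["Y"])
        fit = report.fits["Y"]
        for var, alpha_true in truth.alpha.items():
            if var in fit.coefficients.index and fit.pvalues[var] <= 0.05:
                assert np.sign(fit.coefficients[var]) == np.sign(alpha_true)

    def test_kept_override(self, synth_panel):
        panel, _ = synth_panel
        manual = ["X1", "X4", "X9"]
        report = drv.driver_pipeline(panel, responses=["Y"], kept_override=manual)
        assert report.screening.kept == manual

    def test_sklearn_estimator(self, synth_panel):
        panel, truth = synth_panel
        X = panel[[f"X{i}" for i in range(1, 20)]]
        est = u.DriverRegression().fit(X, panel["Y"])
        assert len(est.kept_) == 7
        assert est.vif_ok_
        # screening may keep a satellite in place of its anchor, so the fit
        # tracks the signal through a correlated proxy rather than exactly
        pred = est.predict(X)
        assert np.corrcoef(pred, panel["Y"])[0, 1] > 0.5
        params = est.get_params()
        assert params["r_threshold"] == 0.75
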