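"""Trajectory model: REML fitting, derivative inference, window fits."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from pitgrowth import features as feat
from pitgrowth import gamm
from pitgrowth import synthetic as syn


def make_two_subject_table(y_fn, noise_sd=0.0, seed=0, n_per=30):
    rng = np.random.default_rng(seed)
    weeks = np.sort(rng.uniform(-15, 85, n_per))
    weeks = np.concatenate([weeks, weeks + 0.37])
    subj = np.repeat(["a", "b"], n_per)
    y = y_fn(weeks) + noise_sd * rng.standard_normal(len(weeks))
    return pd.DataFrame({"subject_id": subj, "weeks": weeks, "y": y})


class TestCar1:
    def test_rho_zero_identity(self):
        np.testing.assert_array_equal(
            gamm.car1_correlation(np.array([0.0, 1.5, 7.0]), 0.0), np.eye(3)
        )

    def test_closed_form(self):
        got = gamm.car1_correlation(np.array([0.0, 1.0, 2.0]), 0.5)
        want = np.array([[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]])
        np.testing.assert_allclose(got, want)

    def test_block_diagonal_across_subjects(self):
        got = gamm.car1_correlation(
            np.array([0.0, 1.0, 0.0]), 0.5, subjects=np.array(["a", "a", "b"])
        )
        assert got[0, 2] == 0.0 and got[0, 1] == 0.5

    def test_invalid_rho(self):
        with pytest.raises(ValueError, match="rho"):
            gamm.car1_correlation(np.array([0.0, 1.0]), 1.0)


class TestFitLimits:
    def test_noiseless_in_span_interpolated(self):
        rng = np.random.default_rng(1)
        tab = make_two_subject_table(lambda w: np.zeros_like(w))
        basis = gamm.SplineBasis.from_times(tab["weeks"].to_numpy(), k=10)
        coef = rng.standard_normal(10)
        tab["y"] = basis.design(tab["weeks"].to_numpy()) @ coef
        fit = gamm.fit_gamm(tab, "y")
        assert np.abs(fit.fitted_full - tab["y"].to_numpy()).max() < 1e-6
        assert fit.adj_r2 > 1 - 1e-6

    def test_linear_truth_small_edf_and_ols_slope(self):
        tab = make_two_subject_table(lambda w: 0.03 * w + 0.2, noise_sd=0.3, seed=2)
        fit = gamm.fit_gamm(tab, "y")
        assert fit.edf <= 1.5
        w = tab["weeks"].to_numpy(); y = tab["y"].to_numpy()
        X = np.column_stack([np.ones_like(w), w])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        se = np.sqrt(
            resid @ resid / (len(y) - 2) * np.linalg.inv(X.T @ X)[1, 1]
        )
        fitted_slope = (
            (fit.predict(np.array([50.0])) - fit.predict(np.array([40.0]))) / 10.0
        ).item()
        assert abs(fitted_slope - beta[1]) <= 2 * se

    def test_infinite_smoothing_matches_gls_line(self):
        tab = make_two_subject_table(lambda w: 0.03 * w + 0.2, noise_sd=0.3, seed=3)
        fit = gamm.fit_gamm(
            tab, "y", fixed_lambda=1e9, fixed_rho=0.0, fixed_gamma=1e-8
        )
        w = tab["weeks"].to_numpy()
        pred = fit.predict(w)
        X = np.column_stack([np.ones_like(w), w])
        line = X @ np.linalg.lstsq(X, tab["y"].to_numpy(), rcond=None)[0]
        assert np.abs(pred - line).max() < 1e-4

    def test_edf_nonincreasing_in_lambda(self, centered_table):
        edfs = [
            gamm.fit_gamm(
                centered_table, "z_vol_anterior",
                fixed_lambda=lam, fixed_rho=0.0, fixed_gamma=1e-8,
            ).edf
            for lam in (1e-3, 1e-1, 1e1, 1e3, 1e5)
        ]
        assert all(a >= b - 1e-8 for a, b in zip(edfs, edfs[1:]))

    def test_reml_optimum_no_worse_than_starts(self, centered_table):
        fit = gamm.fit_gamm(centered_table, "z_vol_anterior")
        assert all(fit.reml <= s + 1e-6 for s in fit.reml_at_starts)

    def test_fit_is_deterministic(self, centered_table):
        a = gamm.fit_gamm(centered_table, "z_vol_anterior")
        b = gamm.fit_gamm(centered_table, "z_vol_anterior")
        np.testing.assert_array_equal(a.beta, b.beta)
        assert a.lam == b.lam and a.rho == b.rho and a.reml == b.reml

    def test_preconditions(self, centered_table):
        one_subj = centered_table[centered_table["subject_id"] == "sub-01"]
        with pytest.raises(ValueError, match="2 subjects"):
            gamm.fit_gamm(one_subj, "z_vol_anterior")
        same_time = centered_table.copy()
        same_time["weeks"] = 5.0
        with pytest.raises(ValueError, match="singular"):
            gamm.fit_gamm(same_time, "z_vol_anterior")


class TestAgainstReferenceImplementation:
    def test_fit_matches_mgcv_gamm_with_corcar1(self, tmp_path):
        """Independent oracle: R's mgcv::gamm with corCAR1 on one replicate.

        Different spline bases, same model family — rho, edf and the
        fitted trajectory should agree closely."""
        import subprocess

        tab = syn.simulate_feature_table(syn.TrajectoryTruth(seed=3))
        fit = gamm.fit_gamm(tab, "y_anterior")
        csv = tmp_path / "rep.csv"
        tab[["subject_id", "weeks", "y_anterior"]].to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            "suppressMessages(library(mgcv))\n"
            f"d <- read.csv('{csv}')\n"
            "d$subject_id <- factor(d$subject_id)\n"
            "m <- gamm(y_anterior ~ s(weeks, k=10), random=list(subject_id=~1),\n"
            "          correlation=corCAR1(form=~weeks|subject_id), data=d)\n"
            "rho <- coef(m$lme$modelStruct$corStruct, unconstrained=FALSE)\n"
            f"write.csv(data.frame(fitted=predict(m$gam, newdata=d)),\n"
            f"          '{tmp_path / 'fit.csv'}', row.names=FALSE)\n"
            "cat(sprintf('%.6f %.4f', rho, summary(m$gam)$edf))\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        rho_ref, edf_ref = map(float, out.stdout.split()[-2:])
        fitted_ref = pd.read_csv(tmp_path / "fit.csv")["fitted"].to_numpy()
        assert abs(fit.rho - rho_ref) <= 0.10
        assert abs(fit.edf - edf_ref) <= 1.5
        assert np.abs(fit.fitted_fixed - fitted_ref).max() <= 0.25


class TestDerivativeInference:
    def test_quadratic_vertex_located(self):
        w0 = 30.0
        tab = make_two_subject_table(lambda w: -0.002 * (w - w0) ** 2, seed=4)
        fit = gamm.fit_gamm(tab, "y", fixed_rho=0.0, fixed_gamma=1e-8)
        band = gamm.derivative_inference(fit, grid_step=0.1)
        maxima = [e for e in band.extrema if e["type"] == "max"]
        assert len(maxima) >= 1
        best = max(maxima, key=lambda e: e["value_sd"])
        assert abs(best["week"] - w0) <= 0.5

    def test_monotone_curve_has_no_extrema_one_interval(self):
        tab = make_two_subject_table(lambda w: 0.02 * w, noise_sd=0.05, seed=5)
        fit = gamm.fit_gamm(tab, "y")
        band = gamm.derivative_inference(fit)
        assert band.extrema == []
        assert len(band.significant_intervals) == 1

    def test_exact_derivative_matches_finite_difference(self, centered_table):
        fit = gamm.fit_gamm(centered_table, "z_vol_anterior")
        band = gamm.derivative_inference(fit, grid_step=0.5)
        h = 1e-5
        fd = (fit.predict(band.grid + h) - fit.predict(band.grid - h)) / (2 * h)
        np.testing.assert_allclose(band.deriv, fd, atol=1e-6)

    def test_intervals_sorted_and_disjoint(self, centered_table):
        fit = gamm.fit_gamm(centered_table, "z_vol_anterior")
        band = gamm.derivative_inference(fit)
        for (a0, a1), (b0, b1) in zip(
            band.significant_intervals, band.significant_intervals[1:]
        ):
            assert a1 < b0
            assert a0 <= a1


class TestWindowFits:
    def test_noiseless_common_line_exact(self):
        tab = make_two_subject_table(lambda w: 0.14 * w - 1.0)
        wfit = gamm.fit_window_lmm(tab, 12, 40, response_column="y")
        assert wfit.slope == pytest.approx(0.14, abs=1e-8)

    def test_shared_slope_matches_per_subject_ols_average(self):
        rng = np.random.default_rng(6)
        rows = []
        for i, icpt in enumerate(rng.normal(0, 0.5, 4)):
            w = np.sort(rng.uniform(12, 40, 15))
            y = icpt + 0.1 * w + 0.2 * rng.standard_normal(15)
            rows.append(pd.DataFrame({"subject_id": f"s{i}", "weeks": w, "y": y}))
        tab = pd.concat(rows, ignore_index=True)
        wfit = gamm.fit_window_lmm(tab, 12, 40, response_column="y")
        slopes = [
            np.polyfit(g["weeks"], g["y"], 1)[0] for _, g in tab.groupby("subject_id")
        ]
        assert abs(wfit.slope - np.mean(slopes)) <= 2 * wfit.slope_se

    def test_window_bounds_enforced(self, centered_table):
        wfit = gamm.fit_window_lmm(centered_table, -5, 12)
        in_window = centered_table[
            (centered_table["weeks"] >= -5) & (centered_table["weeks"] < 12)
        ]
        assert wfit.n_obs == len(in_window)

    def test_too_few_observations_raises(self, centered_table):
        with pytest.raises(ValueError, match="need >= 3"):
            gamm.fit_window_lmm(centered_table, 200.0, 300.0)


class TestDiagnosticsAndLoso:
    def test_whitening_reduces_autocorrelation_with_high_rho(self):
        # weekly visits so the rho=0.6 dependence is visible at lag 1
        reduced = 0
        for seed in range(10):
            truth = syn.TrajectoryTruth(
                rho=0.6, seed=700 + seed,
                time_sampling=np.arange(-2.0, 18.0), time_jitter_weeks=0.3,
            )
            tab = syn.simulate_feature_table(truth)
            fit = gamm.fit_gamm(tab, "y_anterior")
            d = gamm.residual_diagnostics(fit)
            if abs(d["whitened_lag1_autocorr"]) < abs(d["raw_lag1_autocorr"]):
                reduced += 1
        assert reduced >= 9

    def test_independent_case_both_autocorrelations_small(self):
        vals = []
        for seed in range(5):
            truth = syn.TrajectoryTruth(rho=0.0, seed=800 + seed)
            fit = gamm.fit_gamm(syn.simulate_feature_table(truth), "y_anterior")
            d = gamm.residual_diagnostics(fit)
            vals.append(d["raw_lag1_autocorr"])
        assert abs(np.mean(vals)) < 0.25

    def test_per_subject_residual_means_small(self, centered_table):
        fit = gamm.fit_gamm(centered_table, "z_vol_anterior")
        d = gamm.residual_diagnostics(fit)
        for m in d["per_subject_residual_mean"].values():
            assert abs(m) < 0.3

    def test_loso_requires_three_subjects(self, centered_table):
        two = centered_table[centered_table["subject_id"] != "sub-03"]
        with pytest.raises(ValueError, match="3 subjects"):
            gamm.loso_cv(two, "z_vol_anterior")

    def test_loso_perfect_sharing(self):
        truth = syn.TrajectoryTruth(
            subject_intercept_sd=0.0, residual_sd=0.0, rho=0.0, seed=5
        )
        res = gamm.loso_cv(syn.simulate_feature_table(truth), "y_anterior")
        assert all(r >= 0.99 for r in res["per_fold"].values())
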