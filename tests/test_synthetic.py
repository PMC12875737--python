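"""Generator contracts: trajectory shape, CAR(1) structure, phantom geometry."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pitgrowth import synthetic as syn
from pitgrowth.gamm import car1_correlation
from pitgrowth.volumes import ANTERIOR, POSTERIOR
from pitgrowth.fusion import lobe_volume


class TestDefaultTrajectory:
    def test_anchor_values(self):
        f = syn.make_default_trajectory()
        assert f(10.6) == pytest.approx(-0.9, abs=1e-12)
        assert f(34.1) == pytest.approx(1.8, abs=1e-12)
        assert f(-18.0) == 0.0

    def test_extrema_near_printed_weeks(self):
        f = syn.make_default_trajectory()
        g = np.arange(-18, 90, 0.01)
        v = f(g)
        assert abs(g[np.argmin(v)] - 10.6) < 1.5
        assert abs(g[np.argmax(v)] - 34.1) < 1.5

    def test_baseline_before_conception_and_postpartum(self):
        f = syn.make_default_trajectory()
        g = np.arange(-18, 90, 0.05)
        v = f(g)
        assert np.abs(v[g <= -5]).max() < 0.1
        assert np.abs(v[g >= 55]).max() < 0.1

    def test_smooth_second_derivative_exists(self):
        # central second differences stay bounded -> no kinks
        f = syn.make_default_trajectory()
        g = np.arange(-17, 89, 0.01)
        d2 = np.diff(f(g), 2) / 0.01**2
        assert np.all(np.isfinite(d2))
        assert np.abs(d2).max() < 1.0


class TestFeatureTable:
    def test_noiseless_limit_is_f_true(self):
        truth = syn.TrajectoryTruth(
            subject_intercept_sd=0.0, residual_sd=0.0, rho=0.0, seed=0
        )
        tab = syn.simulate_feature_table(truth)
        f = truth.f_true
        np.testing.assert_allclose(
            tab["y_anterior"], f(tab["weeks"].to_numpy()), atol=1e-12
        )

    def test_seed_determinism(self):
        a = syn.simulate_feature_table(syn.TrajectoryTruth(seed=11))
        b = syn.simulate_feature_table(syn.TrajectoryTruth(seed=11))
        pd.testing.assert_frame_equal(a, b)

    def test_raw_volume_mapping(self):
        truth = syn.TrajectoryTruth(seed=2)
        tab = syn.simulate_feature_table(truth)
        sub = tab[tab["subject_id"] == "sub-01"]
        np.testing.assert_allclose(
            sub["vol_anterior_mm3"],
            truth.raw_mean_mm3[0] + truth.raw_sd_mm3[0] * sub["y_anterior"],
        )

    def test_rejects_invalid_rho(self):
        with pytest.raises(ValueError, match="rho"):
            syn.TrajectoryTruth(rho=1.0)

    @pytest.mark.parametrize("rho,expected", [(0.0, 0.0), (0.5, 0.5)])
    def test_adjacent_residual_correlation(self, rho, expected):
        # weekly grid; empirical corr of adjacent residuals over many
        # replicates should approach rho (sample-correlation oracle)
        rng = np.random.default_rng(123)
        t = np.arange(20.0)
        C = car1_correlation(t, rho) if rho else np.eye(20)
        pairs = []
        for _ in range(1000):
            e = np.linalg.cholesky(C + 1e-12 * np.eye(20)) @ rng.standard_normal(20)
            pairs.append(np.column_stack([e[:-1], e[1:]]))
        pairs = np.concatenate(pairs)
        emp = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert emp == pytest.approx(expected, abs=0.03)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        rho=st.floats(min_value=0.0, max_value=0.99),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_car1_matrix_positive_semidefinite(self, rho, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(-18, 90, size=rng.integers(3, 25)))
        corr = car1_correlation(t, rho)
        assert np.allclose(corr, corr.T)
        assert np.linalg.eigvalsh(corr).min() >= -1e-10

    def test_duplicate_times_allowed(self):
        corr = car1_correlation(np.array([1.0, 1.0, 2.0]), 0.5)
        assert corr[0, 1] == 1.0
        assert np.linalg.eigvalsh(corr).min() >= -1e-10


class TestPhantom:
    def test_posterior_hyperintense_required(self):
        with pytest.raises(ValueError, match="hyperintense"):
            syn.PhantomSpec(intensity_posterior=150.0, intensity_anterior=200.0)

    def test_label_volumes_match_analytic_ellipsoids(self, clean_phantom):
        spec, _, lab = clean_phantom
        for code, analytic in [
            (ANTERIOR, spec.anterior_volume_mm3()),
            (POSTERIOR, spec.posterior_volume_mm3()),
        ]:
            assert lobe_volume(lab, code) == pytest.approx(analytic, rel=0.05)

    def test_intensity_ratio_two_before_noise(self, clean_phantom):
        spec, img, lab = clean_phantom
        ant = img.data[lab.mask(ANTERIOR)].mean()
        post = img.data[lab.mask(POSTERIOR)].mean()
        assert post / ant == pytest.approx(2.0, abs=1e-12)

    def test_noop_deformation_gives_identical_sessions(self):
        spec = syn.PhantomSpec(noise_sd=0.0, deformation_scale_mm=0.0)
        truth = syn.TrajectoryTruth(
            subject_intercept_sd=0.0, residual_sd=0.0, rho=0.0,
            sessions_per_subject=3, seed=0,
        )
        # force constant trajectory so volume_scale == 1 in every session
        truth = dataclasses.replace(truth, f_true=syn.flat_trajectory())
        sessions = syn.simulate_image_series(spec, truth, subject=0)
        ref = sessions[0]
        for s in sessions[1:]:
            np.testing.assert_array_equal(s["image"].data, ref["image"].data)
            np.testing.assert_array_equal(s["labels"].data, ref["labels"].data)

    def test_session_volumes_track_trajectory(self):
        spec = syn.PhantomSpec(noise_sd=0.0, deformation_scale_mm=0.0)
        truth = syn.TrajectoryTruth(seed=4, sessions_per_subject=5)
        sessions = syn.simulate_image_series(spec, truth, subject=0)
        for s in sessions:
            measured = lobe_volume(s["labels"], ANTERIOR)
            assert measured == pytest.approx(s["true_vol_anterior_mm3"], rel=0.05)

    def test_boundary_violation_raises(self):
        spec = syn.PhantomSpec(grid_shape=(32, 32, 32))
        with pytest.raises(ValueError, match="boundary"):
            spec.check_in_bounds(anterior_scale=1.0)
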