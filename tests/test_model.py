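"""Warped BLR engine: conjugate-Gaussian oracle, calibration, warp recovery, centiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdnorm import atlas
from pdnorm.model import (
    NormativeModel,
    WarpedBLR,
    compute_zscores,
    deviation_matrix,
    fit_cohort_models,
    PredictiveDistribution,
)
from pdnorm.simulate import GenerativeTruth, ReferenceSpec, generate_reference
from pdnorm.warp import WarpParams, identity_warp


def _linear_data(n=200, sigma=0.3, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-1, 1, n)
    X = np.column_stack([np.ones(n), x])
    y = X @ np.array([1.0, -2.0]) + rng.normal(0, sigma, n)
    return y, X


class TestConjugateOracle:
    def test_posterior_matches_closed_form_at_fixed_hyperparameters(self):
        # independent A-solve oracle: m = (aI + b X'X)^{-1} b X'y
        y, X = _linear_data(n=200)
        alpha, beta = 0.7, 1 / 0.09
        res = WarpedBLR(y, X).fit_fixed(alpha, beta)
        A = alpha * np.eye(2) + beta * X.T @ X
        m = np.linalg.inv(A) @ (beta * X.T @ y)
        np.testing.assert_allclose(res.params, m, rtol=1e-6)
        np.testing.assert_allclose(res.cov_params, np.linalg.inv(A), rtol=1e-6)
        pred = res.predict(X)
        np.testing.assert_allclose(pred.yhat, X @ m, rtol=1e-6)
        np.testing.assert_allclose(
            pred.model_variance, np.einsum("ij,jk,ik->i", X, np.linalg.inv(A), X),
            rtol=1e-6,
        )

    def test_full_fit_matches_oracle_at_its_own_optimum(self):
        y, X = _linear_data(n=2000)
        res = WarpedBLR(y, X).fit(warp=None)
        A = res.alpha * np.eye(2) + res.betas[0] * X.T @ X
        t = res.warp.forward(y)
        m = np.linalg.solve(A, res.betas[0] * X.T @ t)
        np.testing.assert_allclose(res.params, m, rtol=1e-6)

    def test_constant_response_predicts_constant(self):
        X = np.column_stack([np.ones(50), np.linspace(-1, 1, 50)])
        y = np.full(50, 3.3)
        res = WarpedBLR(y, X).fit(warp=None)
        pred = res.predict(X)
        yhat = res.warp.inverse(pred.yhat)
        np.testing.assert_allclose(yhat, 3.3, atol=1e-6)

    def test_degenerate_prior_shrinks_to_zero_latent_mean(self):
        y, X = _linear_data()
        res = WarpedBLR(y, X).fit_fixed(alpha=1e12, betas=1.0)
        np.testing.assert_allclose(res.predict(X).yhat, 0.0, atol=1e-8)

    def test_identical_rows_identical_predictions(self):
        y, X = _linear_data()
        res = WarpedBLR(y, X).fit(warp=None)
        row = np.tile(X[:1], (3, 1))
        pred = res.predict(row)
        assert np.all(pred.yhat == pred.yhat[0])


class TestWarpFit:
    def test_warp_on_beats_warp_off_on_skewed_data(self):
        rng = np.random.default_rng(5)
        n = 2000
        g = rng.standard_normal(n)
        y = 2.5 + 0.8 * np.sinh((np.arcsinh(g) + 0.0) / 1.5)  # heavy shape change
        X = np.ones((n, 1))
        on = WarpedBLR(y, X).fit(warp="sinh-arcsinh", seed=1)
        off = WarpedBLR(y, X).fit(warp=None)
        assert on.nll < off.nll

    def test_warp_shape_parameters_recovered(self):
        rng = np.random.default_rng(6)
        n = 5000
        eps, delta = 0.3, 1.3
        g = rng.standard_normal(n)
        y = 2.5 + 0.8 * np.sinh((np.arcsinh(g) + eps) / delta)
        res = WarpedBLR(y, np.ones((n, 1))).fit(warp="sinh-arcsinh", seed=2)
        assert abs(res.warp.epsilon - eps) / eps < 0.25
        assert abs(res.warp.delta - delta) / delta < 0.25

    def test_model_uncertainty_shrinks_with_training_size(self):
        roi = atlas.ROI_COLUMNS[0]
        out = {}
        for n in (100, 1000):
            spec = ReferenceSpec(n_subjects=n, n_sites=1, site_offset_sd=0.0,
                                 rois=(roi,), seed=31)
            cohort = generate_reference(spec)
            res = NormativeModel.from_cohort(cohort, roi).fit(warp=None)
            out[n] = res.predict_table(cohort).model_variance.mean()
        assert out[1000] < out[100]


class TestZScores:
    def test_zero_when_observation_equals_prediction(self):
        pred = PredictiveDistribution(
            yhat=np.array([2.0]), noise_variance=np.array([1.0]),
            model_variance=np.array([0.5]),
        )
        z = compute_zscores(np.array([2.0]), pred, identity_warp())
        assert z[0] == 0.0

    def test_direct_substitution(self):
        # z = (4 - 2) / sqrt(1 + 1) = sqrt(2)
        pred = PredictiveDistribution(
            yhat=np.array([2.0]), noise_variance=np.array([1.0]),
            model_variance=np.array([1.0]),
        )
        z = compute_zscores(np.array([4.0]), pred, identity_warp())
        np.testing.assert_allclose(z[0], 2.0 / np.sqrt(2.0))

    def test_nonpositive_variance_raises(self):
        pred = PredictiveDistribution(
            yhat=np.array([0.0]), noise_variance=np.array([0.0]),
            model_variance=np.array([0.0]),
        )
        with pytest.raises(FloatingPointError):
            compute_zscores(np.array([1.0]), pred, identity_warp())

    def test_heldout_null_z_is_standard_normal_across_seeds(self):
        # correctly specified model: held-out z passes KS at alpha=.01 in >=95%
        roi = atlas.ROI_COLUMNS[0]
        passes = 0
        n_seeds = 20
        for seed in range(n_seeds):
            spec = ReferenceSpec(n_subjects=2500, n_sites=1, site_offset_sd=0.0,
                                 rois=(roi,), seed=300 + seed)
            cohort = generate_reference(spec)
            model = NormativeModel.from_cohort(cohort.iloc[:2000], roi).fit(warp=None)
            z = model.zscores_table(cohort.iloc[2000:]).to_numpy()
            if stats.kstest(z, "norm").pvalue > 0.01:
                passes += 1
        assert passes >= int(0.95 * n_seeds)

    def test_heldout_calibration_bounds(self, models10, heldout10):
        Z = deviation_matrix(models10, heldout10)
        z = Z.to_numpy().ravel()
        assert abs(z.mean()) < 0.1
        assert 0.85 <= z.var() <= 1.15


class TestCentiles:
    def test_identity_warp_median_equals_mean(self):
        y, X = _linear_data()
        res = WarpedBLR(y, X).fit(warp=None)
        pred = res.predict(X[:5])
        med = res.centiles(X[:5], levels=(50,))[0]
        np.testing.assert_allclose(med, res.warp.inverse(pred.yhat), rtol=1e-10)

    def test_curves_never_cross(self, models10):
        res = next(iter(models10.values()))
        ages = np.linspace(5, 95, 40)
        curves = res.centile_curves(ages, levels=(2.5, 50, 97.5))
        assert (curves[97.5] > curves[50.0]).all()
        assert (curves[50.0] > curves[2.5]).all()

    def test_fitted_upper_centile_tracks_analytic_truth(self):
        roi = atlas.ROI_COLUMNS[0]
        spec = ReferenceSpec(n_subjects=5000, n_sites=1, site_offset_sd=0.0,
                             site_noise_spread=0.0, rois=(roi,), seed=77)
        cohort = generate_reference(spec)
        truth = GenerativeTruth(spec)
        model = NormativeModel.from_cohort(cohort, roi).fit(warp=None)
        ages = np.linspace(20, 80, 13)
        fitted = model.centile_curves(ages, sex=0, levels=(97.5,))[97.5].to_numpy()
        analytic = truth.mean(roi, ages, 0) + 1.959963985 * truth.total_sd[roi]
        assert np.max(np.abs(fitted - analytic)) < 0.1 * truth.total_sd[roi]

    def test_centile_zscore_round_trip(self, models10):
        # a point on the q-centile curve scores z = Phi^{-1}(q)
        roi, res = next(iter(models10.items()))
        ages = np.array([40.0, 60.0])
        q = 75.0
        curve = res.centile_curves(ages, sex=0, levels=(q,))[q].to_numpy()
        table = pd.DataFrame({
            "subject_id": ["a", "b"], "site": res.basis.sites[0], "sex": "F",
            "age": ages, roi: curve,
        })
        z = res.zscores_table(table).to_numpy()
        np.testing.assert_allclose(z, stats.norm.ppf(q / 100), atol=1e-6)

    def test_invalid_level_rejected(self, models10):
        res = next(iter(models10.values()))
        with pytest.raises(ValueError):
            res.centile_curves(np.array([50.0]), levels=(0.0,))


class TestSerialization:
    def test_round_trip_preserves_scores(self, models10, heldout10, tmp_path):
        import json
        from pdnorm.model import NormativeModelResults

        roi, res = next(iter(models10.items()))
        p = tmp_path / "model.json"
        p.write_text(json.dumps(res.to_dict()))
        back = NormativeModelResults.from_dict(json.loads(p.read_text()))
        a = res.zscores_table(heldout10)
        b = back.zscores_table(heldout10)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12)
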