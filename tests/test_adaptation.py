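"""Site transfer: control splits, offset/scale recovery, calibration restoration."""

import numpy as np
import pandas as pd
import pytest

from pdnorm import atlas
from pdnorm.adaptation import (
    AdaptedModel,
    ContaminationError,
    adapt_site,
    adapted_zscores,
    split_controls,
)
from pdnorm.model import NormativeModel
from pdnorm.simulate import GenerativeTruth, ReferenceSpec, generate_reference


def _controls(n, prefix="C"):
    return pd.DataFrame({
        "subject_id": np.repeat([f"{prefix}{i}" for i in range(n)], 2),
        "site": "new", "visit": np.tile([1, 2], n),
    })


class TestSplitControls:
    def test_53_controls_split_26_27(self):
        adapt, test = split_controls(_controls(53), fraction=0.5, seed=0)
        assert adapt["subject_id"].nunique() == 26   # odd extra goes to test
        assert test["subject_id"].nunique() == 27

    def test_minimal_two_controls(self):
        adapt, test = split_controls(_controls(2), fraction=0.5, seed=0)
        assert adapt["subject_id"].nunique() == 1
        assert test["subject_id"].nunique() == 1

    def test_subject_level_split_keeps_visits_together(self):
        adapt, test = split_controls(_controls(10), seed=3)
        assert set(adapt["subject_id"]).isdisjoint(set(test["subject_id"]))
        assert (adapt.groupby("subject_id").size() == 2).all()

    def test_seeded_and_seed_sensitive(self):
        a1, _ = split_controls(_controls(20), seed=5)
        a2, _ = split_controls(_controls(20), seed=5)
        a3, _ = split_controls(_controls(20), seed=6)
        assert set(a1["subject_id"]) == set(a2["subject_id"])
        assert set(a1["subject_id"]) != set(a3["subject_id"])
        assert a3["subject_id"].nunique() == 10

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_controls(_controls(10), fraction=1.5)


def _fit_rois(rois, seed=51, n=1500):
    spec = ReferenceSpec(n_subjects=n, n_sites=1, site_offset_sd=0.0,
                         site_noise_spread=0.0, rois=tuple(rois), seed=seed)
    cohort = generate_reference(spec)
    models = {
        roi: NormativeModel.from_cohort(cohort, roi).fit(warp=None)
        for roi in rois
    }
    return spec, models


def _fit_single_roi(seed=51, n=1500):
    roi = atlas.ROI_COLUMNS[0]
    spec, models = _fit_rois((roi,), seed=seed, n=n)
    return spec, roi, models[roi]


def _new_site_controls(spec, rois, n, shift, scale=1.0, seed=9, site="new",
                       prefix="N"):
    """Controls from an unseen site: reference truth + latent shift/scale.

    ``rois`` may be a single name or a list; noise is independent per ROI
    while the injected site shift is common to all ROIs.
    """
    rois = [rois] if isinstance(rois, str) else list(rois)
    truth = GenerativeTruth(spec)
    rng = np.random.default_rng(seed)
    lo, hi = spec.age_range
    age = rng.uniform(lo, hi, n)
    male = rng.integers(0, 2, n)
    out = pd.DataFrame({
        "subject_id": [f"{prefix}{i}" for i in range(n)],
        "group": "control", "site": site, "sex": np.where(male == 1, "M", "F"),
        "age": age, "visit": 1,
    })
    for roi in rois:
        W = truth.roi_warp(roi)
        out[roi] = W.inverse(
            W.forward(truth.mean(roi, age, male))
            + shift + scale * rng.standard_normal(n)
        )
    return out


class TestAdaptSite:
    def test_null_shift_gives_near_identity_adaptation(self):
        spec, roi, model = _fit_single_roi()
        adapt_set = _new_site_controls(spec, roi, 30, shift=0.0, seed=2)
        am = adapt_site(model, adapt_set)
        # offset is in the model's latent units; convert to generative SD units
        lat_per_sd = model.blr.warp.eta / GenerativeTruth(spec).total_sd[roi]
        assert abs(am.offset) * lat_per_sd < 0.1
        assert 0.8 <= am.scale <= 1.25

    def test_injected_offset_recovered(self):
        # a site shift is common to all of the site's ROIs; its recovery is
        # judged on the across-ROI mean of the per-ROI offsets
        rois = atlas.ROI_COLUMNS[:10]
        spec, models = _fit_rois(rois)
        adapt_set = _new_site_controls(spec, rois, 30, shift=0.5, seed=3)
        recovered = []
        for roi, model in models.items():
            am = adapt_site(model, adapt_set)
            identity = AdaptedModel(base=model, site="new", offset=0.0,
                                    scale=1.0, n_adapt=0)
            total_sd = float(
                np.sqrt(identity.predict_table(adapt_set).total_variance.mean())
            )
            recovered.append(am.offset / total_sd)
        assert abs(np.mean(recovered) - 0.5) <= 0.15

    def test_single_record_falls_back_to_unit_scale(self):
        spec, roi, model = _fit_single_roi()
        one = _new_site_controls(spec, roi, 1, shift=0.3, seed=4)
        with pytest.warns(UserWarning):
            am = adapt_site(model, one)
        assert am.scale == 1.0
        resid = am.base.blr.warp.forward(one[roi].to_numpy()) - (
            am.base.basis.design_from_frame_new_site(one) @ am.base.blr.params
        )
        np.testing.assert_allclose(am.offset, resid[0])

    def test_multi_site_adapt_set_rejected(self):
        spec, roi, model = _fit_single_roi()
        bad = _new_site_controls(spec, roi, 10, shift=0.0)
        bad.loc[bad.index[:5], "site"] = "other"
        with pytest.raises(ValueError, match="multiple sites"):
            adapt_site(model, bad)


class TestAdaptedZScores:
    def test_calibration_restored_after_shift_and_scale(self):
        # injected shift/scale within +-1 SD and x[0.5, 2]; z pooled over ROIs
        rois = atlas.ROI_COLUMNS[:10]
        spec, models = _fit_rois(rois)
        for shift, scale in [(0.5, 1.0), (-1.0, 0.7), (1.0, 1.5)]:
            adapt_set = _new_site_controls(spec, rois, 40, shift, scale, seed=5)
            test_set = _new_site_controls(spec, rois, 25, shift, scale, seed=6,
                                          prefix="T")
            z = np.concatenate([
                adapted_zscores(adapt_site(m, adapt_set), test_set).to_numpy()
                for m in models.values()
            ])
            assert abs(z.mean()) < 0.15, (shift, scale)
            assert 0.8 <= z.var() <= 1.25, (shift, scale)

    def test_unadapted_scores_carry_the_analytic_bias(self):
        spec, roi, model = _fit_single_roi()
        shift = 0.8
        test_set = _new_site_controls(spec, roi, 400, shift, seed=7)
        identity = AdaptedModel(base=model, site="new", offset=0.0, scale=1.0,
                                n_adapt=0)
        z = identity.zscores_table(test_set).to_numpy()
        # the injected latent shift is in units of the generative residual sd,
        # which the model's predictive sd estimates: bias = shift / sd ~ shift
        assert abs(z.mean() - shift) < 0.15

    def test_identity_adaptation_equals_base_scores(self):
        spec, roi, model = _fit_single_roi()
        test_set = _new_site_controls(spec, roi, 20, shift=0.0, seed=8,
                                      site=model.basis.sites[0])
        identity = AdaptedModel(base=model, site=model.basis.sites[0],
                                offset=0.0, scale=1.0, n_adapt=0)
        za = identity.zscores_table(test_set).to_numpy()
        zb = model.zscores_table(test_set).to_numpy()
        np.testing.assert_allclose(za, zb, rtol=1e-10)

    def test_contamination_refused(self):
        spec, roi, model = _fit_single_roi()
        adapt_set = _new_site_controls(spec, roi, 10, shift=0.0, seed=9)
        am = adapt_site(model, adapt_set)
        with pytest.raises(ContaminationError):
            adapted_zscores(am, adapt_set)

    def test_nonpositive_scale_rejected(self):
        spec, roi, model = _fit_single_roi()
        with pytest.raises(ValueError):
            AdaptedModel(base=model, site="x", offset=0.0, scale=0.0, n_adapt=5)
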