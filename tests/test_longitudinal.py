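"""z-diff scoring: centile tracking, null calibration, drift detection, signed maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdnorm import atlas
from pdnorm.adaptation import adapt_site
from pdnorm.longitudinal import (
    change_significance_map,
    compute_zdiff,
    extreme_zdiff_counts,
    zdiff_overlap_map,
)
from pdnorm.model import NormativeModel
from pdnorm.simulate import GenerativeTruth, ReferenceSpec, generate_reference

ROIS = atlas.ROI_COLUMNS[:10]


@pytest.fixture(scope="module")
def longitudinal_setup():
    """Fitted 10-ROI reference + adapted new site with paired control visits."""
    spec = ReferenceSpec(n_subjects=1500, n_sites=1, site_offset_sd=0.0,
                         site_noise_spread=0.0, rois=ROIS, seed=61)
    cohort = generate_reference(spec)
    models = {roi: NormativeModel.from_cohort(cohort, roi).fit(warp=None)
              for roi in ROIS}
    truth = GenerativeTruth(spec)
    return spec, truth, models


def _paired_controls(spec, truth, n, seed, prefix="C", subject_sd=0.8,
                     visit_sd=0.6, drift_latent=None, site_shift=0.3):
    """Two-visit subjects from an unseen site with a stable subject intercept.

    ``drift_latent`` optionally shifts visit-2 latent values per ROI
    (dict roi -> shift in latent units).
    """
    rng = np.random.default_rng(seed)
    age1 = rng.uniform(40, 75, n)
    male = rng.integers(0, 2, n)
    u = rng.normal(0, subject_sd, n)
    frames = []
    for visit in (1, 2):
        age = age1 + (0.0 if visit == 1 else 2.0)
        row = {
            "subject_id": [f"{prefix}{i}" for i in range(n)],
            "group": "control", "site": "new",
            "sex": np.where(male == 1, "M", "F"), "age": age, "visit": visit,
        }
        for roi in ROIS:
            W = truth.roi_warp(roi)
            lat = (W.forward(truth.mean(roi, age, male)) + site_shift + u
                   + visit_sd * rng.standard_normal(n))
            if visit == 2 and drift_latent:
                lat = lat + drift_latent.get(roi, 0.0)
            row[roi] = W.inverse(lat)
        frames.append(pd.DataFrame(row))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="module")
def adapted_models(longitudinal_setup):
    spec, truth, models = longitudinal_setup
    adapt_set = _paired_controls(spec, truth, 40, seed=1, prefix="A")
    return {roi: adapt_site(m, adapt_set) for roi, m in models.items()}, \
        _paired_controls(spec, truth, 100, seed=2, prefix="A")  # denominators


def test_centile_tracking_subject_scores_zero(longitudinal_setup, adapted_models):
    spec, truth, models = longitudinal_setup
    adapted, control_pairs = adapted_models
    roi = ROIS[0]
    am = adapted[roi]
    # place both visits exactly on the adapted 75th centile
    subj = pd.DataFrame({
        "subject_id": ["p1", "p1"], "group": "patient", "site": "new",
        "sex": "F", "age": [60.0, 62.0], "visit": [1, 2],
    })
    pred = am.predict_table(subj)
    q = stats.norm.ppf(0.75)
    lat = pred.yhat + q * np.sqrt(pred.total_variance)
    for r in ROIS:
        subj[r] = adapted[r].base.blr.warp.inverse(
            adapted[r].predict_table(subj).yhat
            + q * np.sqrt(adapted[r].predict_table(subj).total_variance)
        )
    res = compute_zdiff(adapted, subj, control_pairs)
    # ~0 up to the age-variation of the model-uncertainty term
    np.testing.assert_allclose(res.zdiff.to_numpy(), 0.0, atol=1e-2)


def test_driftfree_controls_are_standard_normal(longitudinal_setup, adapted_models):
    spec, truth, models = longitudinal_setup
    adapted, control_pairs = adapted_models
    test_pairs = _paired_controls(spec, truth, 100, seed=3, prefix="T")
    res = compute_zdiff(adapted, test_pairs, control_pairs)
    z = res.zdiff.to_numpy().ravel()
    assert abs(z.mean()) < 0.15
    assert 0.8 <= z.var() <= 1.25


def test_injected_drift_of_one_control_sd_scores_minus_one(
    longitudinal_setup, adapted_models
):
    spec, truth, models = longitudinal_setup
    adapted, control_pairs = adapted_models
    # one control-SD of change, in the denominator's own units
    base = compute_zdiff(
        adapted, _paired_controls(spec, truth, 100, seed=4, prefix="T"),
        control_pairs,
    )
    roi = ROIS[0]
    sd_lat = base.control_change_sd[roi] * adapted[roi].base.blr.warp.eta \
        / truth.total_sd[roi]  # latent units of the generative warp
    drifted = _paired_controls(
        spec, truth, 100, seed=4, prefix="T",
        drift_latent={roi: -1.0 * sd_lat},
    )
    res = compute_zdiff(adapted, drifted, control_pairs)
    assert abs(res.zdiff[roi].mean() - (-1.0)) < 0.2
    # sign coherence: unaffected ROIs stay centred
    others = res.zdiff[[r for r in ROIS if r != roi]].to_numpy()
    assert abs(others.mean()) < 0.15


def test_interpretive_trajectories(longitudinal_setup, adapted_models):
    """Two positive z-scores trending down give z-diff < 0; tracking gives ~0."""
    spec, truth, models = longitudinal_setup
    adapted, control_pairs = adapted_models
    roi = ROIS[0]
    am = adapted[roi]
    subj = pd.DataFrame({
        "subject_id": ["a", "a", "b", "b"], "group": "patient", "site": "new",
        "sex": "M", "age": [60.0, 62.0, 60.0, 62.0], "visit": [1, 2, 1, 2],
    })
    pred = {r: adapted[r].predict_table(subj) for r in ROIS}
    for r in ROIS:
        sd = np.sqrt(pred[r].total_variance)
        # subject a: +1.5 SD then +0.5 SD (downward); b: -1 SD both visits
        zvals = np.array([1.5, 0.5, -1.0, -1.0])
        subj[r] = adapted[r].base.blr.warp.inverse(pred[r].yhat + zvals * sd)
    res = compute_zdiff(adapted, subj, control_pairs)
    assert (res.zdiff.loc["a"] < 0).all()
    np.testing.assert_allclose(res.zdiff.loc["b"].to_numpy(), 0.0, atol=1e-2)


def test_few_control_pairs_refused(longitudinal_setup, adapted_models):
    spec, truth, models = longitudinal_setup
    adapted, _ = adapted_models
    tiny = _paired_controls(spec, truth, 4, seed=5)
    subj = _paired_controls(spec, truth, 10, seed=6, prefix="P")
    with pytest.raises(ValueError, match="control pairs"):
        compute_zdiff(adapted, subj, tiny)


def test_subject_missing_visit_skipped(longitudinal_setup, adapted_models):
    spec, truth, models = longitudinal_setup
    adapted, control_pairs = adapted_models
    subj = _paired_controls(spec, truth, 10, seed=7, prefix="P")
    subj = subj[~((subj["subject_id"] == "P3") & (subj["visit"] == 2))]
    res = compute_zdiff(adapted, subj, control_pairs)
    assert "P3" in res.skipped_subjects
    assert "P3" not in res.zdiff.index


class TestSignificanceMap:
    def test_null_fdr_near_nominal(self):
        rng = np.random.default_rng(8)
        frac = []
        for _ in range(50):
            zd = pd.DataFrame(rng.standard_normal((30, 20)),
                              columns=[f"r{i}" for i in range(20)])
            rep = change_significance_map(zd)
            frac.append(rep["significant"].mean())
        assert np.mean(frac) <= 0.05 + 0.02

    def test_consistent_negative_roi_attains_exact_minimal_p(self):
        rng = np.random.default_rng(9)
        zd = pd.DataFrame({
            "neg": -np.abs(rng.standard_normal(20)) - 0.1,
            "null": rng.standard_normal(20),
        })
        rep = change_significance_map(zd)
        # exact signed-rank null: all 20 signs negative has p = 2 / 2^20
        assert rep.loc["neg", "sign"] == -1
        np.testing.assert_allclose(rep.loc["neg", "pvalue"], 2 * 0.5**20)

    def test_all_zero_column_flagged(self):
        zd = pd.DataFrame({
            "zero": np.zeros(10),
            "var": np.linspace(-1, 1, 10),
        })
        rep = change_significance_map(zd)
        assert rep.loc["zero", "pvalue"] == 1.0 and rep.loc["zero", "sign"] == 0

    def test_too_few_subjects_refused(self):
        zd = pd.DataFrame(np.random.default_rng(0).standard_normal((5, 3)))
        with pytest.raises(ValueError, match="at least 6"):
            change_significance_map(zd)


class TestExtremeZDiff:
    def test_trivial_counts(self):
        zd = pd.DataFrame([[-2.0, 1.97, 0.5]], index=["s"],
                          columns=["a", "b", "c"])
        summ = extreme_zdiff_counts(zd)
        assert summ.negative.iloc[0] == 1 and summ.positive.iloc[0] == 1
        zero = extreme_zdiff_counts(pd.DataFrame([[0.5, -1.0]], index=["s"],
                                                 columns=["a", "b"]))
        assert zero.total.iloc[0] == 0

    def test_null_extreme_rate_near_five_percent(self):
        rng = np.random.default_rng(10)
        zd = pd.DataFrame(rng.standard_normal((400, 50)))
        summ = extreme_zdiff_counts(zd)
        rate = summ.total.sum() / (400 * 50)
        assert abs(rate - 0.05) < 0.01
        m = zdiff_overlap_map(zd, direction="negative")
        assert abs(m.mean() - 2.5) < 1.0
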