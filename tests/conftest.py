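"""Shared fixtures: small synthetic cohorts and session-cached fitted models."""

import warnings

import pytest

from pdnorm import atlas
from pdnorm.adaptation import adapt_cohort, split_controls
from pdnorm.io import apply_qc
from pdnorm.model import fit_cohort_models
from pdnorm.simulate import ClinicalSpec, ReferenceSpec, generate_clinical, generate_reference

warnings.filterwarnings("ignore", message="ages outside the training domain")

ROIS10 = atlas.ROI_COLUMNS[:10]
ROIS12 = tuple(atlas.FOCUS_STRUCTURES) + atlas.THICKNESS_COLUMNS[:8]


@pytest.fixture(scope="session")
def ref_spec10():
    """Single-site lifespan reference, 10 independent ROIs, Gaussian residuals."""
    return ReferenceSpec(
        n_subjects=2500, n_sites=1, site_offset_sd=0.0, rois=ROIS10, seed=101
    )


@pytest.fixture(scope="session")
def ref_cohort10(ref_spec10):
    return generate_reference(ref_spec10)


@pytest.fixture(scope="session")
def models10(ref_cohort10):
    """Warped-BLR normative models fitted on the first 2000 reference subjects."""
    return fit_cohort_models(
        ref_cohort10.iloc[:2000], ROIS10, warp="sinh-arcsinh", seed=0
    )


@pytest.fixture(scope="session")
def heldout10(ref_cohort10):
    """500 held-out null controls from the same generative population."""
    return ref_cohort10.iloc[2000:]


@pytest.fixture(scope="session")
def clin_ref_spec():
    """Two-site reference with the basal-ganglia focus structures included."""
    return ReferenceSpec(n_subjects=1500, n_sites=2, rois=ROIS12, seed=42)


@pytest.fixture(scope="session")
def clin_models(clin_ref_spec):
    ref = generate_reference(clin_ref_spec)
    return fit_cohort_models(ref, list(ROIS12), warp="sinh-arcsinh", seed=0)


@pytest.fixture(scope="session")
def clinical_analysis(clin_ref_spec, clin_models):
    """Default clinical cohort taken through QC, split and site adaptation."""
    clin = generate_clinical(ClinicalSpec(seed=7), clin_ref_spec)
    retained, rep_euler, rep_visits = apply_qc(clin)
    controls = retained[retained["group"] == "control"]
    adapt_set, test_set = split_controls(controls, fraction=0.5, seed=1)
    adapted = adapt_cohort(clin_models, adapt_set)
    return {
        "raw": clin,
        "retained": retained,
        "rep_euler": rep_euler,
        "rep_visits": rep_visits,
        "adapt_set": adapt_set,
        "test_set": test_set,
        "adapted": adapted,
        "patients": retained[retained["group"] == "patient"],
    }
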