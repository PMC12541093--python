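# pdnorm

Normative brain-chart modelling of individual neurodegeneration in
Parkinson's disease (PD).

Group-level case–control contrasts hide the marked heterogeneity of PD:
two patients with the same diagnosis can atrophy in entirely different
regions at entirely different speeds. `pdnorm` implements the normative
modelling alternative for regional morphometry tables (cortical thickness
over the 148 Destrieux parcels, subcortical volume over 37 structures): each
patient is scored against reference brain charts, cross-sectionally and
longitudinally, and the analysis then works with those per-subject deviation
scores. It is written for neuroimaging statisticians who have
FreeSurfer-style regional measures plus covariates, and it ships a synthetic
cohort generator that emulates a two-visit PD study design (patients with
MMP/IM/DM clinical subtypes, healthy controls, MoCA and MDS-UPDRS III
scores, scan-quality metadata), so the entire pipeline is testable without
access to restricted patient data.

## The model

For each region of interest *d*, a warped Bayesian linear regression brain
chart:

```
φ(y_n) = wᵀ φ(x_n) + ε_s ,   ε_s ~ N(0, β_s⁻¹) ,   w ~ N(0, α⁻¹ I)
```

* `φ(x)` — covariate basis: cubic B-spline expansion of age, a sex
  indicator, and fixed-site indicators (reference-cell coding);
* `φ(y)` — a monotone sinh-arcsinh likelihood warp mapping the non-Gaussian
  response to a Gaussian latent space; centiles are obtained by
  inverse-warping;
* `β_s` — per-site noise precision; `α` — prior precision on the weights.

Hyperparameters (α, the β_s, and the warp shape) are set by minimising the
negative log marginal likelihood with Powell's method. Deviation scores
standardise each observation against the predictive distribution:

```
z_nd = (y_nd − ŷ_nd) / sqrt(σ_d² + (σ*²)_d)
```

with `σ_d²` the data-noise variance and `(σ*²)_d` the modelling-uncertainty
variance, evaluated in the warped latent space. A reference model is carried
to a new scanner by **site adaptation**: a held-out control subset (50–50
split) supplies a latent mean offset and a variance scale, after which test
z-scores are centred and unit-variance. Longitudinal change is scored by
**z-diff**: the visit-2 minus visit-1 latent residual of a subject, divided
by the standard deviation of that same quantity across control pairs — a
subject who tracks their centile scores ≈ 0.

Downstream statistics mirror standard practice: extreme-deviation counts
(|z| ≥ 1.96, the 2.5th/97.5th centile cut-off), per-region overlap maps,
one-tailed Mann–Whitney U case–control tests, Wilcoxon signed-rank change
maps with Benjamini–Hochberg FDR, PCA + Spearman brain-behaviour
correlation, and Kruskal–Wallis + Dunn/Bonferroni subtype contrasts.

## Worked example

```python
from pdnorm import (ReferenceSpec, ClinicalSpec, generate_reference,
                    generate_clinical, apply_qc, split_controls, adapt_cohort,
                    fit_cohort_models, case_control_count_test, extreme_counts)
from pdnorm.adaptation import adapted_deviation_matrix
from pdnorm import atlas

rois = tuple(atlas.FOCUS_STRUCTURES) + ("lh_G_temporal_middle_thickness",
                                        "rh_G_cuneus_thickness")
ref_spec = ReferenceSpec(n_subjects=1500, n_sites=2, rois=rois, seed=0)
reference = generate_reference(ref_spec)
models = fit_cohort_models(reference, rois, warp="sinh-arcsinh", seed=0)

clinical = generate_clinical(ClinicalSpec(seed=1), ref_spec)
retained, rep_euler, rep_visits = apply_qc(clinical)
controls = retained[retained.group == "control"]
adapt_set, test_set = split_controls(controls, fraction=0.5, seed=1)
adapted = adapt_cohort(models, adapt_set)

for v in (1, 2):
    Zp = adapted_deviation_matrix(
        adapted, retained[(retained.group == "patient") & (retained.visit == v)])
    Zc = adapted_deviation_matrix(adapted, test_set[test_set.visit == v])
    res = case_control_count_test(extreme_counts(Zp).negative,
                                  extreme_counts(Zc).negative)
    print(f"visit {v}: U = {res.statistic:.1f}, one-tailed p = {res.pvalue:.4f}")
```

prints

```
visit 1: U = 6216.0, one-tailed p = 0.0643
visit 2: U = 7244.5, one-tailed p = 0.0012
```

The default synthetic cohort plants a −0.3 SD patient baseline shift plus
subtype-specific annual decline, so the patient excess in extreme negative
deviations strengthens between visits: at visit 1 the six-region count
difference (0.46 vs 0.22 regions per subject) is only suggestive, while by
visit 2 (1.13 vs 0.33) the one-tailed Mann–Whitney test is clearly
significant. Continuing with the longitudinal z-diff scores and the planted
DM > IM > MMP atrophy ordering:

```python
from pdnorm.longitudinal import compute_zdiff, extreme_zdiff_counts
from pdnorm.subtypes import subtype_contrast

patients = retained[retained.group == "patient"]
zres = compute_zdiff(adapted, patients, adapt_set)
counts = extreme_zdiff_counts(zres.zdiff).negative
labels = (patients.drop_duplicates("subject_id")
          .set_index("subject_id")["subtype"].reindex(zres.zdiff.index))
con = subtype_contrast(counts, labels, zdiff=zres.zdiff)
print(f"Kruskal-Wallis H = {con.H:.2f}, p = {con.pvalue:.2e}")
print(con.overlap_maps.loc["Left-Caudate_volume"].round(1).to_dict())
```

prints

```
Kruskal-Wallis H = 47.12, p = 3.28e-10
{'MMP': 6.3, 'IM': 12.6, 'DM': 41.0, 'undefined': 7.0}
```

i.e. the subtype contrast recovers the planted ordering, with 41% of
diffuse-malignant patients showing extreme longitudinal caudate atrophy
against 6% of mild-motor-predominant patients (the DM–MMP pair has the
smallest Bonferroni-adjusted Dunn p, 1.2e-09).

## Command-line pipeline

The same analysis runs end to end from a shell:

```
pdnorm all --outdir run1 --seed 5            # simulate → qc → fit → adapt →
                                             # deviations → zdiff → behavior → subtypes
pdnorm zdiff --config run.yaml --force       # re-run one stage
```

Every stage writes tab-delimited artifacts plus a JSON manifest (config
hash, input hashes, seed); re-runs with an unchanged config are skipped, and
identical configs give byte-identical outputs. Exit codes: 0 success, 2
config error, 3 data/QC error, 4 numerical failure.

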