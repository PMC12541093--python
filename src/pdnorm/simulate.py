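"""Synthetic reference and clinical cohorts with the structure the analysis assumes.

The real study data (a longitudinal single-site PD cohort plus a restricted
multi-site lifespan reference sample) cannot be redistributed, so this module
generates cohorts with the same statistical skeleton:

* a multi-site lifespan **reference cohort** (ages 2-100) whose per-ROI
  measures follow smooth age trajectories with additive sex effects, per-site
  offsets/noise scales and optionally skewed (sinh-arcsinh-warped) residuals;
* a two-visit **clinical cohort** at a new, unseen site: patients carry a
  baseline shift plus a subtype-specific annualised atrophy rate (DM > IM >
  MMP, strongest in basal-ganglia structures), a subject-level random
  intercept induces within-subject visit correlation, and clinical scores
  (MoCA, MDS-UPDRS III items) are generated from a latent atrophy factor
  through configurable link coefficients;
* quality-control failures (extreme Euler characteristics, missing second
  visits) injected by count so the exclusion cascade has real work to do.

Residuals are produced by pushing Gaussian noise through the inverse of the
engine's own warp family, so the model class used downstream can recover the
generative truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import atlas
from .clinical import UPDRS_ITEM_COLUMNS, N_UPDRS_ITEMS

__all__ = [
    "ReferenceSpec",
    "ClinicalSpec",
    "GenerativeTruth",
    "generate_reference",
    "generate_clinical",
    "cohort_columns",
]

META_COLUMNS = (
    "subject_id", "group", "subtype", "site", "sex", "age", "visit",
    "euler_characteristic", "education_years", "moca_raw", "disease_duration",
    "latent_atrophy",
)


def cohort_columns(rois) -> list[str]:
    return list(META_COLUMNS) + list(UPDRS_ITEM_COLUMNS) + list(rois)


def _roi_warp(truth: "GenerativeTruth", roi: str, spec: "ReferenceSpec"):
    return truth.roi_warp(roi)


@dataclass(frozen=True)
class ReferenceSpec:
    """Design of the synthetic lifespan reference cohort.

    ``noise_scale`` globally multiplies the residual scale (0 gives the
    deterministic limit); ``skew``/``tail`` are the sinh-arcsinh shape of the
    residuals (0/1 = Gaussian).  Trajectory defaults mimic lifespan cortical
    thinning: a childhood peak followed by monotone decline.
    """

    n_subjects: int = 2000
    n_sites: int = 4
    age_range: tuple[float, float] = (2.0, 100.0)
    site_offset_sd: float = 0.3       # per-site mean offset, in residual-SD units
    site_noise_spread: float = 0.2    # per-site noise multiplier ~ U(1-s, 1+s)
    noise_scale: float = 1.0
    skew: float = 0.0
    tail: float = 1.0
    rois: tuple[str, ...] | None = None   # None = full 185-ROI atlas
    trajectory_overrides: dict | None = None  # roi -> (intercept, slope) linear curve
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range low must be < high, got {self.age_range}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.site_noise_spread < 0 or self.site_noise_spread >= 1:
            raise ValueError("site_noise_spread must lie in [0, 1)")
        if self.tail <= 0:
            raise ValueError("tail parameter must be positive")
        if self.n_sites < 1:
            raise ValueError("need at least one site")

    @property
    def roi_list(self) -> tuple[str, ...]:
        return self.rois if self.rois is not None else atlas.ROI_COLUMNS

    @property
    def site_labels(self) -> tuple[str, ...]:
        return tuple(f"site{i + 1:02d}" for i in range(self.n_sites))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        d["rois"] = list(self.rois) if self.rois is not None else None
        return d


class GenerativeTruth:
    """Per-ROI generative parameters derived deterministically from a ReferenceSpec.

    Each ROI gets a smooth mean age trajectory (cubic spline through control
    points rising to a childhood peak and declining monotonically afterwards),
    a residual SD in measurement units, and an additive sex effect.  Traits
    are keyed to the ROI's position in the full atlas, so a subset cohort
    shares trajectories with the full one.
    """

    def __init__(self, spec: ReferenceSpec):
        from scipy.interpolate import CubicSpline

        self.spec = spec
        self._traj = {}
        self.total_sd = {}
        self.sex_effect = {}
        overrides = spec.trajectory_overrides or {}
        for roi in spec.roi_list:
            idx = atlas.ROI_COLUMNS.index(roi)
            r = np.random.default_rng([spec.seed, 1000 + idx])
            if atlas.is_thickness(roi):
                peak_val = r.uniform(2.4, 3.1)
                scale = 1.0
                sd = r.uniform(0.10, 0.18)
                sex_eff = r.uniform(-0.3, 0.3) * sd
            else:
                peak_val = 10 ** r.uniform(3.2, 4.3)
                scale = peak_val
                sd = 0.07 * peak_val
                sex_eff = r.uniform(0.1, 0.6) * sd
            peak_age = r.uniform(7.0, 12.0)
            knots_age = np.array([2.0, peak_age, 30.0, 60.0, 100.0])
            knots_val = peak_val * np.array([0.92, 1.0, 0.97, 0.90, 0.80])
            if roi in overrides:
                icpt, slope = overrides[roi]
                self._traj[roi] = (lambda a, i=icpt, s=slope: i + s * np.asarray(a))
            else:
                cs = CubicSpline(knots_age, knots_val)
                self._traj[roi] = cs
            self.total_sd[roi] = sd
            self.sex_effect[roi] = sex_eff
        self.anchor = {
            roi: float(self.trajectory(roi, 60.0)) for roi in spec.roi_list
        }
        # per-site offsets (measurement units) and noise multipliers
        self.site_offset = {}
        self.site_noise_mult = {}
        self.site_euler_base = {}
        for s_i, site in enumerate(spec.site_labels):
            r = np.random.default_rng([spec.seed, 2000 + s_i])
            offs = r.normal(0.0, spec.site_offset_sd, size=len(atlas.ROI_COLUMNS))
            for roi in spec.roi_list:
                self.site_offset[(site, roi)] = (
                    offs[atlas.ROI_COLUMNS.index(roi)] * self.total_sd[roi]
                )
            self.site_noise_mult[site] = float(
                r.uniform(1 - spec.site_noise_spread, 1 + spec.site_noise_spread)
            )
            self.site_euler_base[site] = int(np.round(r.uniform(-80, -30)))

    def roi_warp(self, roi: str):
        """The ROI's generative warp: measurement units <-> Gaussian latent space.

        Measures are drawn as ``y = W^{-1}(W(mean) + residual)`` with the
        residual Gaussian in the latent space, so the modelling engine's warp
        family contains the generative truth exactly.  With skew 0 and tail 1
        this reduces to the additive model ``y = mean + total_sd * residual``.
        """
        from .warp import WarpParams

        return WarpParams(
            xi=self.anchor[roi], eta=self.total_sd[roi],
            epsilon=self.spec.skew, delta=self.spec.tail,
        )

    def trajectory(self, roi, age):
        return np.asarray(self._traj[roi](np.asarray(age, dtype=float)), dtype=float)

    def mean(self, roi, age, male):
        return self.trajectory(roi, age) + self.sex_effect[roi] * np.asarray(
            male, dtype=float
        )


def _euler(rng, n, base):
    # dispersed integer surface-defect counts; natural spread stays below the
    # robust-z QC cutoff so injected failures alone determine exclusions
    return (base - rng.poisson(6.0, size=n)).astype(int)


def _empty_table(rois) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object if c in
                                      ("subject_id", "group", "subtype", "site", "sex")
                                      else float)
                         for c in cohort_columns(rois)})


def generate_reference(spec: ReferenceSpec) -> pd.DataFrame:
    """One record per subject; measures = trajectory(age, sex) + site offset + warped noise."""
    rois = spec.roi_list
    if spec.n_subjects == 0:
        return _empty_table(rois)
    truth = GenerativeTruth(spec)
    rng = np.random.default_rng([spec.seed, 1])
    n = spec.n_subjects
    lo, hi = spec.age_range
    age = rng.uniform(lo, hi, size=n)
    male = rng.integers(0, 2, size=n)
    site_idx = rng.integers(0, spec.n_sites, size=n)
    sites = np.array(spec.site_labels, dtype=object)[site_idx]

    data = {
        "subject_id": np.array([f"REF{i + 1:05d}" for i in range(n)], dtype=object),
        "group": np.full(n, "reference", dtype=object),
        "subtype": np.full(n, "", dtype=object),
        "site": sites,
        "sex": np.where(male == 1, "M", "F").astype(object),
        "age": age,
        "visit": np.ones(n, dtype=int),
        "euler_characteristic": np.concatenate(
            [
                _euler(
                    np.random.default_rng([spec.seed, 5, s_i]),
                    int((site_idx == s_i).sum()),
                    truth.site_euler_base[spec.site_labels[s_i]],
                )
                for s_i in range(spec.n_sites)
            ]
        )[np.argsort(np.argsort(site_idx, kind="stable"), kind="stable")],
        "education_years": np.full(n, np.nan),
        "moca_raw": np.full(n, np.nan),
        "disease_duration": np.full(n, np.nan),
        "latent_atrophy": np.full(n, np.nan),
    }
    for c in UPDRS_ITEM_COLUMNS:
        data[c] = np.full(n, np.nan)

    mult = np.array([truth.site_noise_mult[s] for s in sites], dtype=float)
    for roi in rois:
        g = rng.standard_normal(n)
        offs = np.array([truth.site_offset[(s, roi)] for s in sites])
        mean_y = truth.mean(roi, age, male) + offs
        W = _roi_warp(truth, roi, spec)
        data[roi] = W.inverse(W.forward(mean_y) + spec.noise_scale * mult * g)
    return pd.DataFrame(data, columns=cohort_columns(rois))


@dataclass(frozen=True)
class ClinicalSpec:
    """Design of the two-visit synthetic clinical cohort at one new site.

    Disease effects are expressed in units of the reference residual SD:
    ``baseline_shift`` moves patient measures at visit 1, the subtype
    ``atrophy_rates`` (SD/year, ordered DM >= IM >= MMP) act over the visit
    interval, amplified by ``focus_multiplier`` in the configured
    basal-ganglia focus structures.  ``subject_sd``/``visit_noise_sd``
    partition the unit residual into a stable subject intercept and
    visit-level measurement noise (their squares sum to ~1 so cross-sectional
    calibration against the reference model holds).
    """

    n_patients: int = 457
    n_controls: int = 56
    subtype_counts: dict = field(
        default_factory=lambda: {"MMP": 191, "IM": 135, "DM": 39}
    )
    visit_interval: float = 2.0
    baseline_shift: float = -0.3
    baseline_heterogeneity: float = 0.2
    atrophy_rates: dict = field(
        default_factory=lambda: {"DM": 0.25, "IM": 0.15, "MMP": 0.08, "undefined": 0.12}
    )
    focus_multiplier: float = 2.5
    subject_sd: float = 0.8
    visit_noise_sd: float = 0.6
    # clinical links: latent atrophy factor -> scores
    moca_link: tuple[float, float] = (1.2, 1.8)    # (coefficient, noise sd), points
    updrs_item_link: float = 0.05                   # per-item probability shift per SD
    updrs_item_p: tuple[float, float] = (31.75 / 132.0, 37.76 / 132.0)
    subtype_severity: dict = field(
        default_factory=lambda: {"MMP": -0.3, "IM": 0.1, "DM": 0.8, "undefined": 0.2,
                                 "": 0.0}
    )
    # QC-failure plan
    n_euler_fail_patients: int = 16
    n_euler_fail_controls: int = 2
    n_single_visit_patients: int = 33
    n_single_visit_controls: int = 1
    site: str = "PPP"
    seed: int = 0

    def __post_init__(self):
        if self.visit_interval <= 0:
            raise ValueError("visit_interval must be positive")
        doomed = self.n_euler_fail_patients + self.n_single_visit_patients
        clean = self.n_patients - doomed
        if sum(self.subtype_counts.values()) > self.n_patients:
            raise ValueError("subtype counts exceed n_patients")
        if sum(self.subtype_counts.values()) > clean:
            raise ValueError(
                "subtype counts exceed the number of QC-surviving patients "
                f"({clean}); reduce counts or the QC-failure plan"
            )
        r = self.atrophy_rates
        if not (r.get("DM", 0) >= r.get("IM", 0) >= r.get("MMP", 0)):
            raise ValueError("atrophy rates must be ordered DM >= IM >= MMP")
        if min(r.values()) < 0:
            raise ValueError("atrophy rates must be >= 0")
        if self.n_controls < self.n_euler_fail_controls + self.n_single_visit_controls:
            raise ValueError("QC-failure plan exceeds n_controls")

    def to_dict(self) -> dict:
        return asdict(self)


def _assign_subtypes(spec: ClinicalSpec, rng) -> np.ndarray:
    """Subtype labels for all patients; configured counts land on QC survivors."""
    doomed = spec.n_euler_fail_patients + spec.n_single_visit_patients
    clean = spec.n_patients - doomed
    labels = []
    for name, cnt in spec.subtype_counts.items():
        labels.extend([name] * cnt)
    labels.extend(["undefined"] * (clean - len(labels)))
    labels = np.array(labels, dtype=object)
    rng.shuffle(labels)
    pool = list(spec.subtype_counts) + ["undefined"]
    probs = np.array([spec.subtype_counts.get(p, clean - sum(spec.subtype_counts.values()))
                      for p in pool], dtype=float)
    probs /= probs.sum()
    doomed_labels = rng.choice(pool, size=doomed, p=probs)
    return np.concatenate([labels, doomed_labels])


def generate_clinical(spec: ClinicalSpec, reference: ReferenceSpec) -> pd.DataFrame:
    """Two-visit clinical cohort drawn from the reference generative truth.

    The first ``n_patients - n_euler_fail - n_single_visit`` patients (after
    an internal shuffle) carry exactly the configured subtype counts, so the
    post-QC table reproduces them; QC failures are injected only into the
    remaining subjects.
    """
    rois = reference.roi_list
    truth = GenerativeTruth(reference)
    rng = np.random.default_rng([spec.seed, 2])
    site_rng = np.random.default_rng([spec.seed, 3])

    # unseen-site effects, drawn like a reference site's
    site_off = {
        roi: site_rng.normal(0.0, reference.site_offset_sd) * truth.total_sd[roi]
        for roi in rois
    }
    site_mult = float(
        site_rng.uniform(1 - reference.site_noise_spread,
                         1 + reference.site_noise_spread)
    ) if reference.site_noise_spread > 0 else 1.0
    euler_base = int(np.round(site_rng.uniform(-80, -30)))

    n_pat, n_con = spec.n_patients, spec.n_controls
    n = n_pat + n_con
    is_patient = np.concatenate([np.ones(n_pat, bool), np.zeros(n_con, bool)])
    subject_id = np.array(
        [f"PAT{i + 1:04d}" for i in range(n_pat)]
        + [f"CON{i + 1:04d}" for i in range(n_con)],
        dtype=object,
    )
    subtype = np.concatenate(
        [_assign_subtypes(spec, rng), np.full(n_con, "", dtype=object)]
    )

    # QC-failure flags: patients after the clean block, controls at the tail
    doomed_pat = spec.n_euler_fail_patients + spec.n_single_visit_patients
    clean_pat = n_pat - doomed_pat
    euler_fail = np.zeros(n, bool)
    single_visit = np.zeros(n, bool)
    euler_fail[clean_pat : clean_pat + spec.n_euler_fail_patients] = True
    single_visit[clean_pat + spec.n_euler_fail_patients : n_pat] = True
    clean_con = n_con - spec.n_euler_fail_controls - spec.n_single_visit_controls
    euler_fail[n_pat + clean_con : n_pat + clean_con + spec.n_euler_fail_controls] = True
    single_visit[n_pat + clean_con + spec.n_euler_fail_controls :] = True

    age1 = np.where(
        is_patient,
        np.clip(rng.normal(61.0, 8.7, n), 31.0, 82.0),
        np.clip(rng.normal(60.4, 9.8, n), 35.0, 82.0),
    )
    male = rng.random(n) < 0.55
    u = rng.normal(0.0, spec.subject_sd, n)          # subject intercept, SD units
    het = rng.normal(0.0, 1.0, n)                    # baseline-severity heterogeneity

    sev_shift = np.array([spec.subtype_severity.get(s, 0.0) for s in subtype])
    latent_atrophy = np.where(
        is_patient, -(u / spec.subject_sd) + sev_shift, -(u / spec.subject_sd)
    )

    base_dev = np.where(
        is_patient, spec.baseline_shift + spec.baseline_heterogeneity * het, 0.0
    )
    rate = np.where(
        is_patient,
        np.array([spec.atrophy_rates.get(s, 0.0) for s in subtype]),
        0.0,
    )

    edu = np.round(
        np.clip(np.where(is_patient, rng.normal(17.2, 4.1, n), rng.normal(16.1, 3.2, n)),
                6, 24)
    )
    dur1 = np.where(is_patient, np.clip(rng.normal(31.7, 17.6, n), 1.0, 60.0), np.nan)

    records = []
    for visit in (1, 2):
        dt = 0.0 if visit == 1 else spec.visit_interval
        age = age1 + dt
        row = {
            "subject_id": subject_id,
            "group": np.where(is_patient, "patient", "control").astype(object),
            "subtype": subtype,
            "site": np.full(n, spec.site, dtype=object),
            "sex": np.where(male, "M", "F").astype(object),
            "age": age,
            "visit": np.full(n, visit, dtype=int),
            "education_years": edu,
            "disease_duration": np.where(is_patient, dur1 + 12.0 * dt, np.nan),
            "latent_atrophy": latent_atrophy,
        }
        ec = _euler(np.random.default_rng([spec.seed, 6, visit]), n, euler_base)
        if visit == 1:
            fail_at_1 = rng.random(n) < 0.5
        ec = np.where(euler_fail & (fail_at_1 if visit == 1 else ~fail_at_1),
                      euler_base - 600, ec)
        row["euler_characteristic"] = ec

        # clinical scores from the latent atrophy factor
        p0 = spec.updrs_item_p[visit - 1]
        sev = latent_atrophy + rng.normal(0, 0.5, n)
        p_item = np.clip(p0 + spec.updrs_item_link * sev, 0.01, 0.96)
        items = rng.binomial(4, p_item[:, None] * np.ones((1, N_UPDRS_ITEMS)))
        items = items.astype(float)
        items[~is_patient] = np.nan
        coef, noise_sd = spec.moca_link
        moca_base = np.where(is_patient, 27.0 if visit == 1 else 26.0,
                             27.7 if visit == 1 else 27.3)
        moca = np.clip(
            np.round(moca_base - coef * latent_atrophy + rng.normal(0, noise_sd, n)),
            0, 30,
        )
        # undefined subtype: mask clinical fields (non-random missingness)
        undef = subtype == "undefined"
        if visit == 1:
            mask_kind = rng.integers(0, 3, n)  # 0: moca, 1: updrs, 2: both
        moca = np.where(undef & np.isin(mask_kind, (0, 2)), np.nan, moca)
        items[undef & np.isin(mask_kind, (1, 2))] = np.nan
        row["moca_raw"] = moca
        for k, c in enumerate(UPDRS_ITEM_COLUMNS):
            row[c] = items[:, k]

        for roi in rois:
            f = spec.focus_multiplier if roi in atlas.FOCUS_STRUCTURES else 1.0
            g = rng.standard_normal(n)
            sd_units = (
                base_dev
                - rate * f * dt
                + u
                + spec.visit_noise_sd * g
            )
            mean_y = truth.mean(roi, age, male.astype(float)) + site_off[roi]
            W = _roi_warp(truth, roi, reference)
            row[roi] = W.inverse(W.forward(mean_y) + site_mult * sd_units)
        records.append(pd.DataFrame(row, columns=cohort_columns(rois)))

    table = pd.concat(records, ignore_index=True)
    # single-visit subjects lose visit 2 (a deterministic handful lose visit 1)
    lose_v1 = np.zeros(n, bool)
    lose_v1[np.flatnonzero(single_visit)[::5]] = True
    drop_v1 = np.concatenate([single_visit & lose_v1, np.zeros(n, bool)])
    drop_v2 = np.concatenate([np.zeros(n, bool), single_visit & ~lose_v1])
    table = table.loc[~(drop_v1 | drop_v2)].reset_index(drop=True)
    return table
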