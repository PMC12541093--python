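"""Longitudinal deviation (z-diff) scoring against an adapted cross-sectional model.

The z-diff statistic compares an individual's change in latent residual
between two visits to the variability of that change among healthy control
pairs from the same site:

    z-diff_nd = (resid2_nd - resid1_nd) / sd_d(control resid2 - resid1)

where each residual is taken against the age-appropriate adapted prediction,
so the expected movement along the centile is subtracted out.  A subject who
tracks their centile scores ~0; healthy drift-free controls are ~standard
normal under the framework's core assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .adaptation import AdaptedModel
from .cross_sectional import (
    EXTREME_THRESHOLD,
    ExtremeSummary,
    extreme_counts,
    overlap_map,
)

__all__ = [
    "ZDiffResult",
    "compute_zdiff",
    "change_significance_map",
    "extreme_zdiff_counts",
    "zdiff_overlap_map",
]

MIN_CONTROL_PAIRS = 5
MIN_SUBJECTS_WILCOXON = 6


@dataclass
class ZDiffResult:
    """Subjects-by-ROIs z-diff matrix with its control-pair normalisation."""

    zdiff: pd.DataFrame
    control_change_sd: pd.Series   #: per-ROI sd of control residual change
    n_control_pairs: int
    visit_interval: float | None = None
    skipped_subjects: tuple[str, ...] = ()


def _paired_visits(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Align visit-1 and visit-2 rows by subject; report subjects missing a visit."""
    v1 = table[table["visit"] == 1].set_index("subject_id")
    v2 = table[table["visit"] == 2].set_index("subject_id")
    common = v1.index.intersection(v2.index)
    skipped = sorted(set(table["subject_id"].astype(str)) - set(map(str, common)))
    return v1.loc[common], v2.loc[common], skipped


def compute_zdiff(
    adapted: dict[str, AdaptedModel],
    subjects: pd.DataFrame,
    control_pairs: pd.DataFrame,
    annualize: bool = False,
) -> ZDiffResult:
    """z-diff scores for two-visit subjects, normalised by control-pair change.

    ``subjects`` and ``control_pairs`` are long tables with visit 1 and 2
    rows; control pairs should come from the adaptation subset so test
    controls stay held out.  Subjects missing a visit are skipped with a log
    entry in the result.  ``annualize`` divides each change by its visit
    interval in years (off by default; the design interval is ~2 years).
    """
    c1, c2, c_skip = _paired_visits(control_pairs)
    if len(c1) < MIN_CONTROL_PAIRS:
        raise ValueError(
            f"need at least {MIN_CONTROL_PAIRS} control pairs for a stable "
            f"denominator, got {len(c1)}"
        )
    s1, s2, skipped = _paired_visits(subjects)
    if len(s1) == 0:
        raise ValueError("no subject has both visits")

    interval = float(np.median(s2["age"].to_numpy() - s1["age"].to_numpy()))
    zd = {}
    sds = {}
    for roi, am in adapted.items():
        rc = am.latent_residuals(c2.reset_index()) - am.latent_residuals(c1.reset_index())
        rs = am.latent_residuals(s2.reset_index()) - am.latent_residuals(s1.reset_index())
        if annualize:
            c_dt = (c2["age"].to_numpy() - c1["age"].to_numpy())
            s_dt = (s2["age"].to_numpy() - s1["age"].to_numpy())
            rc = rc / c_dt
            rs = rs / s_dt
        sd = float(np.std(rc, ddof=1))
        if sd <= 0:
            raise ValueError(f"control change variance is zero for ROI {roi!r}")
        zd[roi] = rs / sd
        sds[roi] = sd
    zdiff = pd.DataFrame(zd, index=pd.Index(s1.index, name="subject_id"))
    return ZDiffResult(
        zdiff=zdiff,
        control_change_sd=pd.Series(sds, name="control_change_sd"),
        n_control_pairs=len(c1),
        visit_interval=interval,
        skipped_subjects=tuple(skipped),
    )


def change_significance_map(zdiff: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-ROI Wilcoxon signed-rank of z-diff against 0, signed and BH-corrected.

    The sign of each p-value is the direction of the median z-diff (signed
    p-value maps); all-zero ROI columns get p = 1 and sign 0.
    """
    n = len(zdiff)
    if n < MIN_SUBJECTS_WILCOXON:
        raise ValueError(
            f"need at least {MIN_SUBJECTS_WILCOXON} subjects for the signed-rank "
            f"map, got {n}"
        )
    rows = []
    for roi in zdiff.columns:
        x = zdiff[roi].to_numpy(dtype=float)
        med = float(np.median(x))
        if np.all(x == 0):
            rows.append({"roi": roi, "pvalue": 1.0, "sign": 0, "median": 0.0})
            continue
        res = stats.wilcoxon(x, zero_method="wilcox")
        sign = int(np.sign(med)) if med != 0 else int(np.sign(np.mean(x)))
        rows.append({"roi": roi, "pvalue": float(res.pvalue), "sign": sign,
                     "median": med})
    out = pd.DataFrame(rows).set_index("roi")
    rej, p_adj, _, _ = multipletests(out["pvalue"], alpha=alpha, method="fdr_bh")
    out["pvalue_fdr"] = p_adj
    out["significant"] = rej
    out["signed_pvalue"] = out["sign"] * out["pvalue_fdr"]
    return out


def extreme_zdiff_counts(
    zdiff: pd.DataFrame, threshold: float = EXTREME_THRESHOLD
) -> ExtremeSummary:
    """Extreme z-diff counts per subject; same contract as the cross-sectional counts."""
    return extreme_counts(zdiff, threshold=threshold)


def zdiff_overlap_map(
    zdiff: pd.DataFrame, threshold: float = EXTREME_THRESHOLD,
    direction: str = "negative",
) -> pd.Series:
    return overlap_map(zdiff, threshold=threshold, direction=direction)
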