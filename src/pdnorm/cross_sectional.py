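"""Extreme-deviation burden summaries and case-control tests.

An extreme deviation is |z| at or beyond the threshold implied by the 2.5th /
97.5th centiles of a standard normal (1.96 by default, boundary inclusive).
Per-subject counts of extreme negative/positive deviations are compared
between patients and controls with a one-tailed Mann-Whitney U test; spatial
overlap maps give, per ROI, the percentage of subjects deviating there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EXTREME_THRESHOLD",
    "extreme_threshold",
    "ExtremeSummary",
    "extreme_counts",
    "overlap_map",
    "case_control_count_test",
    "duration_correlation",
]

#: two-sided tail centiles defining an extreme deviation
LOWER_TAIL_CENTILE = 2.5
UPPER_TAIL_CENTILE = 97.5


def extreme_threshold(lower_centile: float = LOWER_TAIL_CENTILE) -> float:
    """|z| cut-off implied by the stated tail centiles of a standard normal."""
    return float(-stats.norm.ppf(lower_centile / 100.0))


EXTREME_THRESHOLD = 1.96  # extreme_threshold() to printed precision


@dataclass
class ExtremeSummary:
    """Per-subject extreme-deviation counts at a fixed threshold."""

    negative: pd.Series  #: count of z <= -threshold per subject
    positive: pd.Series  #: count of z >= +threshold per subject
    threshold: float
    n_rois: int

    @property
    def total(self) -> pd.Series:
        return self.negative + self.positive


def extreme_counts(Z: pd.DataFrame, threshold: float = EXTREME_THRESHOLD) -> ExtremeSummary:
    """Count extreme negative and positive deviations per subject (boundary inclusive)."""
    if Z.size and not np.all(np.isfinite(Z.to_numpy(dtype=float))):
        raise ValueError("deviation matrix contains non-finite entries")
    vals = Z.to_numpy(dtype=float) if Z.size else np.empty((len(Z), Z.shape[1]))
    neg = pd.Series((vals <= -threshold).sum(axis=1), index=Z.index, name="n_negative")
    pos = pd.Series((vals >= threshold).sum(axis=1), index=Z.index, name="n_positive")
    return ExtremeSummary(negative=neg, positive=pos, threshold=threshold,
                          n_rois=Z.shape[1])


def overlap_map(
    Z: pd.DataFrame, threshold: float = EXTREME_THRESHOLD, direction: str = "negative"
) -> pd.Series:
    """Per-ROI percentage of subjects with an extreme deviation in that ROI."""
    if len(Z) == 0:
        raise ValueError("overlap map needs at least one subject")
    vals = Z.to_numpy(dtype=float)
    if direction == "negative":
        hits = vals <= -threshold
    elif direction == "positive":
        hits = vals >= threshold
    else:
        raise ValueError(f"direction must be 'negative' or 'positive', got {direction!r}")
    return pd.Series(100.0 * hits.mean(axis=0), index=Z.columns, name=f"overlap_{direction}_pct")


@dataclass
class CountTestResult:
    statistic: float   #: Mann-Whitney U for the first (patient) sample
    pvalue: float      #: one-tailed
    tail: str
    method: str        #: 'exact' or 'asymptotic'
    degenerate: bool = False


def case_control_count_test(
    patient_counts, control_counts, tail: str = "greater"
) -> CountTestResult:
    """One-tailed Mann-Whitney U test on extreme-deviation counts.

    Exact enumeration when both groups are small (n <= 20) and tie-free,
    normal approximation with tie correction otherwise.  With all values
    identical across both groups the test is degenerate and p = 0.5 is
    reported with a flag.
    """
    x = np.asarray(patient_counts, dtype=float)
    y = np.asarray(control_counts, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if tail not in ("greater", "less"):
        raise ValueError(f"tail must be 'greater' or 'less', got {tail!r}")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return CountTestResult(
            statistic=x.size * y.size / 2.0, pvalue=0.5, tail=tail,
            method="degenerate", degenerate=True,
        )
    has_ties = np.unique(pooled).size < pooled.size
    small = max(x.size, y.size) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=tail, method=method)
    return CountTestResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue), tail=tail,
        method=method,
    )


def duration_correlation(
    scores: pd.DataFrame, disease_duration: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Spearman correlation of component scores with disease duration, BH-corrected.

    ``scores`` holds one column per principal component (subjects in rows);
    rows with missing duration are dropped pairwise.
    """
    rows = []
    for col in scores.columns:
        pair = pd.concat([scores[col], disease_duration], axis=1).dropna()
        if len(pair) < 3:
            raise ValueError(f"fewer than 3 complete pairs for component {col!r}")
        rho, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
        rows.append({"component": col, "rho": float(rho), "pvalue": float(p),
                     "n": len(pair)})
    out = pd.DataFrame(rows)
    rej, p_adj, _, _ = multipletests(out["pvalue"], alpha=alpha, method="fdr_bh")
    out["pvalue_fdr"] = p_adj
    out["significant"] = rej
    return out
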