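"""Subtype contrasts of longitudinal extreme-deviation burden.

Patients carry clinical subtype labels — mild-motor-predominant (MMP),
intermediate (IM), diffuse-malignant (DM), and 'undefined' for substantial
missing data (included by default, since missingness may be non-random) —
and their per-subject extreme z-diff counts are contrasted with a
Kruskal-Wallis omnibus test followed by Dunn's pairwise post-hoc test with
Bonferroni correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cross_sectional import EXTREME_THRESHOLD, overlap_map

__all__ = ["kruskal_wallis", "dunn_posthoc", "subtype_overlap_maps",
           "SubtypeContrast", "subtype_contrast"]


def kruskal_wallis(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p over labelled groups.

    Empty groups are dropped with a warning; fewer than two surviving groups
    is an error.  With all observations identical H = 0 and p = 1.
    """
    kept = {}
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            warnings.warn(f"group {name!r} is empty and was dropped", stacklevel=2)
            continue
        kept[name] = vals
    if len(kept) < 2:
        raise ValueError("need at least 2 nonempty groups")
    pooled = np.concatenate(list(kept.values()))
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*kept.values())
    return float(H), float(p)


@dataclass
class DunnRow:
    group_a: str
    group_b: str
    z: float
    pvalue: float
    pvalue_bonferroni: float
    small_sample: bool = False


def dunn_posthoc(
    groups: dict[str, np.ndarray], correction: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's pairwise rank-mean comparisons with tie-corrected variance.

    For each pair, z = (Rbar_a - Rbar_b) / sqrt( (N(N+1)/12 - T) (1/n_a + 1/n_b) )
    with tie term T = sum(t^3 - t) / (12 (N - 1)) over tied-value groups of the
    pooled ranks; two-sided p from the normal, Bonferroni-adjusted over all
    C(k, 2) pairs.  Pairs involving a singleton group are flagged.
    """
    if correction != "bonferroni":
        raise ValueError(f"unsupported correction {correction!r}")
    names = [n for n in groups if np.asarray(groups[n]).size > 0]
    if len(names) < 2:
        raise ValueError("need at least 2 nonempty groups")
    vals = [np.asarray(groups[n], dtype=float) for n in names]
    pooled = np.concatenate(vals)
    N = pooled.size
    ranks = stats.rankdata(pooled)  # average-rank ties
    splits = np.cumsum([v.size for v in vals])[:-1]
    rank_groups = np.split(ranks, splits)
    mean_ranks = {n: float(r.mean()) for n, r in zip(names, rank_groups)}
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in itertools.combinations(names, 2):
        na, nb = groups[a].__len__(), groups[b].__len__()
        se = np.sqrt(base_var * (1.0 / na + 1.0 / nb))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append(
            DunnRow(
                group_a=a, group_b=b, z=float(z), pvalue=p,
                pvalue_bonferroni=min(1.0, p * n_pairs),
                small_sample=(na < 2 or nb < 2),
            ).__dict__
        )
    return pd.DataFrame(rows)


def subtype_overlap_maps(
    zdiff: pd.DataFrame,
    labels: pd.Series,
    threshold: float = EXTREME_THRESHOLD,
    direction: str = "negative",
    admissible: tuple[str, ...] = ("MMP", "IM", "DM", "undefined"),
) -> pd.DataFrame:
    """Per-subtype per-ROI overlap percentages of extreme z-diff scores."""
    labels = labels.reindex(zdiff.index)
    unknown = sorted(set(labels.dropna().unique()) - set(admissible))
    if unknown:
        raise ValueError(
            f"unknown subtype label(s) {unknown}; admissible: {list(admissible)}"
        )
    if labels.isna().any():
        raise ValueError("every subject must carry a subtype label")
    maps = {}
    for name in admissible:
        members = zdiff.loc[labels == name]
        if len(members):
            maps[name] = overlap_map(members, threshold=threshold, direction=direction)
    return pd.DataFrame(maps)


@dataclass
class SubtypeContrast:
    """Omnibus + pairwise contrast of extreme-count distributions across subtypes."""

    group_counts: dict[str, np.ndarray]
    H: float
    pvalue: float
    pairwise: pd.DataFrame
    overlap_maps: pd.DataFrame = field(default=None)

    def to_text(self) -> str:
        lines = [f"kruskal_wallis_H\t{self.H:.6g}", f"kruskal_wallis_p\t{self.pvalue:.6g}",
                 f"n_pairwise\t{len(self.pairwise)}"]
        for _, r in self.pairwise.iterrows():
            lines.append(
                f"dunn\t{r['group_a']}\t{r['group_b']}\t{r['z']:.4f}"
                f"\t{r['pvalue']:.6g}\t{r['pvalue_bonferroni']:.6g}"
            )
        return "\n".join(lines) + "\n"


def subtype_contrast(
    counts: pd.Series,
    labels: pd.Series,
    zdiff: pd.DataFrame | None = None,
    include_undefined: bool = True,
    threshold: float = EXTREME_THRESHOLD,
) -> SubtypeContrast:
    """Full subtype analysis of per-subject extreme z-diff counts.

    ``counts`` and ``labels`` are indexed by subject.  The undefined group is
    a fourth group by default; drop it with ``include_undefined=False``.
    """
    labels = labels.reindex(counts.index)
    order = ["MMP", "IM", "DM"] + (["undefined"] if include_undefined else [])
    groups = {
        name: counts[labels == name].to_numpy(dtype=float)
        for name in order
        if (labels == name).any()
    }
    H, p = kruskal_wallis(groups)
    pairwise = dunn_posthoc(groups)
    maps = None
    if zdiff is not None:
        maps = subtype_overlap_maps(zdiff, labels, threshold=threshold)
    return SubtypeContrast(group_counts=groups, H=H, pvalue=p,
                           pairwise=pairwise, overlap_maps=maps)
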