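"""Dimension reduction of deviation matrices and brain-behaviour correlation.

Deviation (or z-diff) matrices are reduced with PCA — components are already
on the z scale, so columns are centred but not re-standardised by default —
and the subject scores of the top components are Spearman-correlated with
clinical measures (MoCA, UPDRS total and sub-scores, or their visit-to-visit
change scores), with Benjamini-Hochberg FDR control over the declared test
family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComponentDecomposition",
    "pca_reduce",
    "spearman_fdr",
    "change_scores",
    "elbow_k",
]


@dataclass
class ComponentDecomposition:
    """Column-centred PCA of a subjects-by-ROIs matrix.

    Loadings are orthonormal (ROIs x k); a deterministic sign convention
    makes the largest-magnitude loading of each component positive.
    """

    loadings: pd.DataFrame        #: ROIs x components
    scores: pd.DataFrame          #: subjects x components
    explained_variance_ratio: np.ndarray
    column_means: pd.Series
    k_selection: str              #: 'fixed' or 'elbow'

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def reconstruct(self) -> pd.DataFrame:
        """scores x loadings' + column means; exact at full rank."""
        rec = self.scores.to_numpy() @ self.loadings.to_numpy().T
        return pd.DataFrame(
            rec + self.column_means.to_numpy()[None, :],
            index=self.scores.index,
            columns=self.loadings.index,
        )


def elbow_k(explained_variance_ratio: np.ndarray) -> int:
    """Maximum-curvature (elbow) pick on the explained-variance curve.

    Uses the maximal distance to the chord between the first and last point
    of the scree curve; returns at least 1.
    """
    y = np.asarray(explained_variance_ratio, dtype=float)
    m = y.size
    if m <= 2:
        return m
    x = np.arange(m, dtype=float)
    p0, p1 = np.array([x[0], y[0]]), np.array([x[-1], y[-1]])
    chord = p1 - p0
    chord /= np.linalg.norm(chord)
    rel = np.stack([x, y], axis=1) - p0
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    return int(np.argmax(dist)) + 1


def pca_reduce(M: pd.DataFrame, k: int | str = 3, standardize: bool = False
               ) -> ComponentDecomposition:
    """PCA of a deviation matrix keeping ``k`` components (or the elbow pick).

    ``k='elbow'`` fits the full decomposition, applies maximum curvature to
    the explained-variance curve, and truncates; otherwise ``k`` is a fixed
    count (must not exceed the matrix rank bound).
    """
    X = M.to_numpy(dtype=float)
    n, d = X.shape
    max_k = min(n, d)
    selection = "fixed"
    if isinstance(k, str):
        if k != "elbow":
            raise ValueError(f"k must be an integer or 'elbow', got {k!r}")
        selection = "elbow"
        k_fit = max_k
    else:
        if not 0 < k <= max_k:
            raise ValueError(f"k must lie in 1..{max_k}, got {k}")
        if n <= k:
            raise ValueError("need more subjects than components")
        k_fit = k
    means = X.mean(axis=0)
    if standardize:
        sds = X.std(axis=0, ddof=0)
        sds[sds == 0] = 1.0
        X = (X - means) / sds
        means = np.zeros(d)
    pca = PCA(n_components=k_fit, svd_solver="full")
    scores = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    if selection == "elbow":
        k_keep = elbow_k(evr)
        scores = scores[:, :k_keep]
        comps = pca.components_[:k_keep]
        evr = evr[:k_keep]
    else:
        k_keep = k_fit
        comps = pca.components_
    # deterministic orientation: largest-|loading| entry of each PC is positive
    for j in range(k_keep):
        i = np.argmax(np.abs(comps[j]))
        if comps[j, i] < 0:
            comps[j] = -comps[j]
            scores[:, j] = -scores[:, j]
    names = [f"PC{j + 1}" for j in range(k_keep)]
    return ComponentDecomposition(
        loadings=pd.DataFrame(comps.T, index=M.columns, columns=names),
        scores=pd.DataFrame(scores, index=M.index, columns=names),
        explained_variance_ratio=evr,
        column_means=pd.Series(means, index=M.columns),
        k_selection=selection,
    )


def spearman_fdr(
    scores: pd.DataFrame,
    clinical: pd.DataFrame,
    family: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlations over a declared (component, measure) test family.

    ``family`` defaults to the full cross of score columns with clinical
    columns; BH step-up runs across exactly that family.  Zero-variance
    measures are flagged and excluded from the family with a note.
    """
    if family is None:
        family = [(c, m) for c in scores.columns for m in clinical.columns]
    rows = []
    for comp, meas in family:
        pair = pd.concat([scores[comp], clinical[meas]], axis=1).dropna()
        if len(pair) < 3:
            raise ValueError(
                f"fewer than 3 complete pairs for ({comp}, {meas})"
            )
        if pair.iloc[:, 1].nunique() == 1 or pair.iloc[:, 0].nunique() == 1:
            rows.append({"component": comp, "measure": meas, "rho": np.nan,
                         "pvalue": np.nan, "n": len(pair), "note": "zero-variance"})
            continue
        rho, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
        rows.append({"component": comp, "measure": meas, "rho": float(rho),
                     "pvalue": float(p), "n": len(pair), "note": ""})
    out = pd.DataFrame(rows)
    tested = out["pvalue"].notna()
    p_adj = np.full(len(out), np.nan)
    rej = np.zeros(len(out), dtype=bool)
    if tested.any():
        rej_t, p_t, _, _ = multipletests(
            out.loc[tested, "pvalue"], alpha=alpha, method="fdr_bh"
        )
        p_adj[tested.to_numpy()] = p_t
        rej[tested.to_numpy()] = rej_t
    out["pvalue_fdr"] = p_adj
    out["significant"] = rej
    return out


def change_scores(
    visit1: pd.DataFrame, visit2: pd.DataFrame, mode: str = "absolute"
) -> pd.DataFrame:
    """Visit-to-visit clinical change: t2 - t1, or 100 x (t2 - t1) / t1.

    Inputs are indexed by subject with one column per measure; subjects are
    matched on the index.  In percent mode a zero baseline is flagged missing
    (NaN), not infinite.
    """
    if mode not in ("absolute", "percent"):
        raise ValueError(f"mode must be 'absolute' or 'percent', got {mode!r}")
    common = visit1.index.intersection(visit2.index)
    t1 = visit1.loc[common].astype(float)
    t2 = visit2.loc[common].astype(float)
    diff = t2 - t1
    if mode == "absolute":
        return diff
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * diff / t1
    return pct.mask(t1 == 0)
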