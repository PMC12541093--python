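"""Transfer of a fitted reference model to a new site via held-out controls.

A pre-fitted normative model carries the reference sites' offsets and noise
precisions, but a new scanner/site needs re-centering and re-scaling before
its z-scores are unbiased.  The adaptation estimates, in the warped latent
space where the model is Gaussian,

* a mean offset  = mean latent residual of the adaptation controls, and
* a variance scale = ratio of their residual variance to the model-predicted
  predictive variance,

and applies both to the predictive distribution at that site.  Adaptation and
test subsets are split at the subject level (both visits travel together) and
kept disjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import NormativeModelResults, PredictiveDistribution, compute_zscores

__all__ = ["split_controls", "adapt_site", "AdaptedModel", "adapt_cohort",
           "adapted_deviation_matrix", "ContaminationError"]

MIN_ADAPT_RECOMMENDED = 5


class ContaminationError(ValueError):
    """Adaptation and test subsets share subjects."""


def split_controls(
    controls: pd.DataFrame, fraction: float = 0.5, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject-level split of controls into (adaptation, test) subsets.

    Sizes differ by at most one subject; with an odd count the extra subject
    goes to the test set (evaluation power is favoured).  Seeded and
    reproducible.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    subjects = pd.unique(controls["subject_id"])
    if len(subjects) < 2:
        raise ValueError("need at least 2 control subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(subjects))
    n_adapt = int(np.floor(len(subjects) * fraction))
    adapt_ids = set(subjects[perm[:n_adapt]])
    mask = controls["subject_id"].isin(adapt_ids)
    return (
        controls.loc[mask].reset_index(drop=True),
        controls.loc[~mask].reset_index(drop=True),
    )


@dataclass
class AdaptedModel:
    """A reference normative model plus one new site's offset/scale correction."""

    base: NormativeModelResults
    site: str
    offset: float               #: latent mean offset of the new site
    scale: float                #: multiplicative correction of total predictive variance
    n_adapt: int
    adapt_subjects: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("variance scale must be positive")

    @property
    def roi(self) -> str:
        return self.base.roi

    def predict_table(self, table: pd.DataFrame) -> PredictiveDistribution:
        """Offset/scale-corrected predictive distribution at the adapted site."""
        X = self.base.basis.design_from_frame_new_site(table)
        blr = self.base.blr
        yhat = X @ blr.params + self.offset
        model_var = np.einsum("ij,jk,ik->i", X, blr.cov_params, X)
        noise_var = np.full(X.shape[0], float(np.mean(1.0 / blr.betas)))
        return PredictiveDistribution(
            yhat=yhat,
            noise_variance=self.scale * noise_var,
            model_variance=self.scale * np.maximum(model_var, 0.0),
        )

    def latent_residuals(self, table: pd.DataFrame) -> np.ndarray:
        """Warped observation minus adapted latent prediction, per record."""
        pred = self.predict_table(table)
        t = self.base.blr.warp.forward(table[self.roi].to_numpy(dtype=float))
        return t - pred.yhat

    def zscores_table(self, table: pd.DataFrame) -> pd.Series:
        pred = self.predict_table(table)
        z = compute_zscores(
            table[self.roi].to_numpy(dtype=float), pred, self.base.blr.warp
        )
        return pd.Series(z, index=table.index, name=self.roi)

    def to_dict(self) -> dict:
        return {
            "schema": "pdnorm-adapted-roi/1",
            "site": self.site,
            "offset": self.offset,
            "scale": self.scale,
            "n_adapt": self.n_adapt,
            "adapt_subjects": list(self.adapt_subjects),
            "base": self.base.to_dict(),
        }


def adapt_site(model: NormativeModelResults, adapt_set: pd.DataFrame) -> AdaptedModel:
    """Estimate a new site's latent offset and variance scale from controls.

    The offset is the mean latent residual of the adaptation records against
    the un-adapted reference prediction; the scale is the ratio of their
    residual variance to the model's predicted total variance.  A single
    adaptation record fixes the offset but falls back to scale 1 with a
    warning.
    """
    sites = pd.unique(adapt_set["site"].astype(str))
    if len(sites) != 1:
        raise ValueError(f"adaptation set spans multiple sites: {list(sites)}")
    if len(adapt_set) == 0:
        raise ValueError("adaptation set is empty")
    n_subj = adapt_set["subject_id"].nunique()
    if n_subj < MIN_ADAPT_RECOMMENDED:
        warnings.warn(
            f"only {n_subj} adaptation subject(s); offset/scale estimates are noisy",
            stacklevel=2,
        )
    blr = model.blr
    X = model.basis.design_from_frame_new_site(adapt_set)
    yhat = X @ blr.params
    t = blr.warp.forward(adapt_set[model.roi].to_numpy(dtype=float))
    resid = t - yhat
    offset = float(np.mean(resid))
    if len(resid) < 2:
        warnings.warn("single adaptation record: variance scale fixed at 1",
                      stacklevel=2)
        scale = 1.0
    else:
        model_var = np.einsum("ij,jk,ik->i", X, blr.cov_params, X)
        predicted = float(np.mean(1.0 / blr.betas) + np.mean(np.maximum(model_var, 0)))
        scale = float(np.var(resid, ddof=1) / predicted)
    return AdaptedModel(
        base=model,
        site=str(sites[0]),
        offset=offset,
        scale=scale,
        n_adapt=int(n_subj),
        adapt_subjects=tuple(sorted(map(str, pd.unique(adapt_set["subject_id"])))),
    )


def _check_disjoint(adapted: AdaptedModel, table: pd.DataFrame) -> None:
    overlap = set(map(str, pd.unique(table["subject_id"]))) & set(
        adapted.adapt_subjects
    )
    if overlap:
        raise ContaminationError(
            f"test set shares {len(overlap)} subject(s) with the adaptation set, "
            f"e.g. {sorted(overlap)[:3]}"
        )


def adapted_zscores(adapted: AdaptedModel, test_set: pd.DataFrame) -> pd.Series:
    """Deviation scores at the adapted site; refuses adapt/test contamination."""
    _check_disjoint(adapted, test_set)
    return adapted.zscores_table(test_set)


def adapt_cohort(
    models: dict[str, NormativeModelResults], adapt_set: pd.DataFrame
) -> dict[str, AdaptedModel]:
    return {roi: adapt_site(m, adapt_set) for roi, m in models.items()}


def adapted_deviation_matrix(
    adapted: dict[str, AdaptedModel], table: pd.DataFrame, check_disjoint: bool = True
) -> pd.DataFrame:
    """Subjects-by-ROIs z-score matrix at the adapted site."""
    cols = {}
    for roi, am in adapted.items():
        if check_disjoint:
            _check_disjoint(am, table)
        cols[roi] = am.zscores_table(table)
    Z = pd.DataFrame(cols, index=table.index)
    Z.index = pd.Index(table["subject_id"], name="subject_id")
    return Z
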