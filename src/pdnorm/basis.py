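"""Covariate design: cubic B-spline age expansion + sex + fixed-site indicators."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline


class UnknownSiteError(KeyError):
    """Raised when a design row carries a site label the layout has not seen.

    Scoring data from a new site must go through the site-adaptation path
    rather than the reference design matrix.
    """


@dataclass(frozen=True)
class BSplineBasis:
    """Layout of the design matrix: age spline block, sex column, site block.

    The spline block is a degree-3 B-spline basis over ``age_range`` with
    ``n_interior_knots`` evenly spaced interior knots; it forms a partition of
    unity at every age in the domain, so no separate intercept column is
    needed.  Sites use reference-cell coding: the first label in ``sites`` is
    the baseline and contributes no column.
    """

    age_range: tuple[float, float]
    sites: tuple[str, ...]
    n_interior_knots: int = 5
    degree: int = 3
    knots: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range low must be < high, got {self.age_range}")
        if len(self.sites) == 0:
            raise ValueError("at least one site label is required")
        interior = np.linspace(lo, hi, self.n_interior_knots + 2)[1:-1]
        knots = np.concatenate(
            [np.full(self.degree + 1, lo), interior, np.full(self.degree + 1, hi)]
        )
        object.__setattr__(self, "knots", knots)

    @property
    def n_spline(self) -> int:
        return self.n_interior_knots + self.degree + 1

    @property
    def n_columns(self) -> int:
        return self.n_spline + 1 + len(self.sites) - 1

    @property
    def column_names(self) -> list[str]:
        names = [f"age_bs{i}" for i in range(self.n_spline)]
        names.append("sex")
        names.extend(f"site[{s}]" for s in self.sites[1:])
        return names

    def spline_block(self, age: np.ndarray) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        lo, hi = self.age_range
        if np.any(age < lo) or np.any(age > hi):
            warnings.warn(
                "ages outside the training domain were clipped to the boundary",
                stacklevel=3,
            )
            age = np.clip(age, lo, hi)
        return BSpline.design_matrix(age, self.knots, self.degree).toarray()

    def design_matrix(
        self, age: np.ndarray, sex: np.ndarray, site: np.ndarray
    ) -> np.ndarray:
        """Assemble the full design matrix for records with given covariates.

        ``sex`` is coded 0/1 (female/male); ``site`` holds string labels known
        to the layout.
        """
        age = np.asarray(age, dtype=float)
        sex = np.asarray(sex, dtype=float)
        site = np.asarray(site, dtype=object)
        unknown = sorted(set(site) - set(self.sites))
        if unknown:
            raise UnknownSiteError(
                f"site label(s) {unknown} not in the reference layout; "
                "score them through site adaptation instead"
            )
        blocks = [self.spline_block(age), sex[:, None]]
        for s in self.sites[1:]:
            blocks.append((site == s).astype(float)[:, None])
        return np.hstack(blocks)

    def design_matrix_new_site(self, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
        """Design rows for records from a site unseen at training time.

        The site-indicator block is all zeros (reference-site coding); the
        site-adaptation offset/scale absorbs the new site's effects.
        """
        age = np.asarray(age, dtype=float)
        sex = np.asarray(sex, dtype=float)
        blocks = [
            self.spline_block(age),
            sex[:, None],
            np.zeros((age.shape[0], len(self.sites) - 1)),
        ]
        return np.hstack(blocks)

    def design_from_frame_new_site(self, table: pd.DataFrame) -> np.ndarray:
        sex = table["sex"]
        if sex.dtype == object:
            sex = sex.map({"F": 0, "M": 1})
        return self.design_matrix_new_site(table["age"].to_numpy(), sex.to_numpy())

    def design_from_frame(self, table: pd.DataFrame) -> np.ndarray:
        sex = table["sex"]
        if sex.dtype == object:
            sex = sex.map({"F": 0, "M": 1})
        return self.design_matrix(
            table["age"].to_numpy(), sex.to_numpy(), table["site"].astype(str).to_numpy()
        )
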