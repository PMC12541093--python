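"""Cohort table reading/writing and the pre-modelling exclusion cascade.

Tables are tab-delimited text with a one-line header, mirroring FreeSurfer
regional-stats exports merged with covariates.  The QC cascade is (1) a
per-site robust Euler-characteristic outlier filter and (2) a both-visits
completeness requirement, applied in that order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = (
    "subject_id", "group", "site", "sex", "age", "visit", "euler_characteristic",
)

_NUMERIC_COLUMNS = ("age", "visit", "euler_characteristic")


class CohortValidationError(ValueError):
    pass


@dataclass
class QCReport:
    """Accounting of one exclusion step: input = retained + excluded."""

    n_input: int
    n_retained: int
    n_excluded_euler: int = 0
    n_excluded_missing_visit: int = 0
    reasons: dict[str, str] = field(default_factory=dict)  # subject_id -> reason
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        total = self.n_retained + self.n_excluded_euler + self.n_excluded_missing_visit
        if self.n_input != total:
            raise ValueError(
                f"QC accounting broken: {self.n_input} input != {total} retained+excluded"
            )

    def to_text(self) -> str:
        lines = [
            f"n_input\t{self.n_input}",
            f"n_retained\t{self.n_retained}",
            f"n_excluded_euler\t{self.n_excluded_euler}",
            f"n_excluded_missing_visit\t{self.n_excluded_missing_visit}",
        ]
        for w in self.warnings:
            lines.append(f"warning\t{w}")
        for sid, reason in sorted(self.reasons.items()):
            lines.append(f"excluded\t{sid}\t{reason}")
        return "\n".join(lines) + "\n"


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a tab-delimited cohort table.

    Unknown columns are preserved untouched; a missing required column raises
    an error naming it, and malformed numeric cells raise a row-addressed
    parse error.
    """
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise CohortValidationError(
            f"cohort table {path} is missing required column(s): {', '.join(missing)}"
        )
    for col in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortValidationError(
                f"malformed numeric value {table[col].iloc[row]!r} in column "
                f"{col!r} at data row {row + 1}"
            )
        table[col] = coerced
    return table


def euler_filter(
    table: pd.DataFrame, cutoff: float = 5.0, variant: str = "median-mad"
) -> tuple[pd.DataFrame, QCReport]:
    """Exclude subjects with a site-normalised Euler characteristic above ``cutoff``.

    Per site, the statistic is the median-centred magnitude scaled by
    1.4826 x MAD (a robust z).  A subject is excluded entirely if any of their
    visits exceeds the cutoff.  Sites with fewer than 3 records are passed
    through unfiltered with a warning flag in the report.
    """
    if variant != "median-mad":
        raise ValueError(f"unknown Euler normalisation variant {variant!r}")
    n_input = len(table)
    bad_subjects: set[str] = set()
    report_warnings: list[str] = []
    if np.isfinite(cutoff):
        for site, grp in table.groupby("site", sort=False):
            ec = grp["euler_characteristic"].to_numpy(dtype=float)
            if len(grp) < 3:
                report_warnings.append(
                    f"site {site!r} has {len(grp)} record(s); Euler filter skipped"
                )
                continue
            med = np.median(ec)
            mad = np.median(np.abs(ec - med))
            if mad == 0:
                continue  # zero spread: nothing is an outlier
            robust_z = np.abs(ec - med) / (1.4826 * mad)
            flagged = grp.loc[robust_z > cutoff, "subject_id"]
            bad_subjects.update(flagged.astype(str))
    mask = table["subject_id"].astype(str).isin(bad_subjects)
    retained = table.loc[~mask].reset_index(drop=True)
    report = QCReport(
        n_input=n_input,
        n_retained=len(retained),
        n_excluded_euler=int(mask.sum()),
        reasons={sid: "euler" for sid in sorted(bad_subjects)},
        warnings=report_warnings,
    )
    return retained, report


def require_both_visits(table: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """Retain only subjects with exactly one record at each of visits 1 and 2."""
    visits = table["visit"].to_numpy()
    if not np.isin(visits, (1, 2)).all():
        raise CohortValidationError("visit index must be 1 or 2")
    dup = table.duplicated(subset=["subject_id", "visit"])
    if dup.any():
        sid = table.loc[dup, "subject_id"].iloc[0]
        raise CohortValidationError(f"duplicate (subject, visit) pair for {sid!r}")
    counts = table.groupby("subject_id")["visit"].nunique()
    complete = set(counts.index[counts == 2])
    mask = table["subject_id"].isin(complete)
    retained = table.loc[mask].reset_index(drop=True)
    removed = sorted(set(table["subject_id"]) - complete)
    report = QCReport(
        n_input=len(table),
        n_retained=len(retained),
        n_excluded_missing_visit=int((~mask).sum()),
        reasons={str(s): "missing_visit" for s in removed},
    )
    return retained, report


def apply_qc(
    table: pd.DataFrame, cutoff: float = 5.0
) -> tuple[pd.DataFrame, QCReport, QCReport]:
    """Full cascade: Euler filter first, then the both-visits requirement."""
    t1, rep_euler = euler_filter(table, cutoff=cutoff)
    t2, rep_visits = require_both_visits(t1)
    return t2, rep_euler, rep_visits
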