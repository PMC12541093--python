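"""Clinical summary scores: MDS-UPDRS part III composites and education-adjusted MoCA.

The motor examination yields 33 item scores (items 3.1-3.18, several items
scored per limb/side), each on a 0-4 severity scale.  The total is the sum of
all 33; sub-scores group items into bradykinesia (11 scores), rigidity (5),
resting tremor (6), action tremor (4) and postural instability / gait
difficulty (PIGD, 5) via a configurable item-index map.

The Montreal Cognitive Assessment (MoCA, 0-30) is education-adjusted: one
point is added to the raw total if the participant has 12 or fewer years of
education, capped at 30.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_UPDRS_ITEMS = 33

# 0-based indices into the 33-score part-III vector, laid out in item order:
# 3.1 speech(0), 3.2 facial(1), 3.3 rigidity x5 (2-6), 3.4 finger tapping x2
# (7-8), 3.5 hand movements x2 (9-10), 3.6 pronation-supination x2 (11-12),
# 3.7 toe tapping x2 (13-14), 3.8 leg agility x2 (15-16), 3.9 arising (17),
# 3.10 gait (18), 3.11 freezing (19), 3.12 postural stability (20),
# 3.13 posture (21), 3.14 global bradykinesia (22), 3.15 postural tremor x2
# (23-24), 3.16 kinetic tremor x2 (25-26), 3.17 rest tremor amplitude x5
# (27-31), 3.18 rest tremor constancy (32).
DEFAULT_SUBSCALE_MAP: dict[str, tuple[int, ...]] = {
    "bradykinesia": (7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 22),
    "rigidity": (2, 3, 4, 5, 6),
    "resting_tremor": (27, 28, 29, 30, 31, 32),
    "action_tremor": (23, 24, 25, 26),
    "pigd": (17, 18, 19, 20, 21),
}

UPDRS_ITEM_COLUMNS = tuple(f"updrs3_i{k:02d}" for k in range(1, N_UPDRS_ITEMS + 1))


class ClinicalValidationError(ValueError):
    pass


def adjusted_moca(raw_moca: float, education_years: float) -> float:
    """Education-adjusted MoCA: +1 point at <= 12 years of education, capped at 30."""
    if not 0 <= raw_moca <= 30:
        raise ClinicalValidationError(f"raw MoCA must be in 0-30, got {raw_moca}")
    if education_years <= 12:
        return min(raw_moca + 1, 30)
    return raw_moca


def score_clinical(
    items,
    education_years: float,
    raw_moca: float,
    subscale_map: dict[str, tuple[int, ...]] | None = None,
) -> dict[str, float]:
    """Summary scores from one subject's UPDRS III item vector and MoCA.

    Returns a dict with ``updrs_total``, the five sub-scores, and
    ``moca_adjusted``.
    """
    items = np.asarray(items, dtype=float)
    if items.shape != (N_UPDRS_ITEMS,):
        raise ClinicalValidationError(
            f"expected {N_UPDRS_ITEMS} UPDRS III item scores, got shape {items.shape}"
        )
    if np.any((items < 0) | (items > 4)):
        raise ClinicalValidationError("UPDRS item scores must lie in 0-4")
    smap = subscale_map if subscale_map is not None else DEFAULT_SUBSCALE_MAP
    out = {"updrs_total": float(items.sum())}
    for name, idx in smap.items():
        out[f"updrs_{name}"] = float(items[list(idx)].sum())
    out["moca_adjusted"] = float(adjusted_moca(raw_moca, education_years))
    return out


def score_clinical_frame(
    table: pd.DataFrame, subscale_map: dict[str, tuple[int, ...]] | None = None
) -> pd.DataFrame:
    """Vectorised clinical scoring over a cohort table.

    Rows with any missing UPDRS item get NaN motor scores; rows with missing
    MoCA or education get NaN adjusted MoCA.
    """
    smap = subscale_map if subscale_map is not None else DEFAULT_SUBSCALE_MAP
    items = table[list(UPDRS_ITEM_COLUMNS)].to_numpy(dtype=float)
    valid = np.all(np.isfinite(items), axis=1)
    if np.any((items[valid] < 0) | (items[valid] > 4)):
        raise ClinicalValidationError("UPDRS item scores must lie in 0-4")
    out = pd.DataFrame(index=table.index)
    total = items.sum(axis=1)
    total[~valid] = np.nan
    out["updrs_total"] = total
    for name, idx in smap.items():
        sub = items[:, list(idx)].sum(axis=1)
        sub[~valid] = np.nan
        out[f"updrs_{name}"] = sub
    moca = table["moca_raw"].to_numpy(dtype=float)
    edu = table["education_years"].to_numpy(dtype=float)
    adj = np.where(edu <= 12, np.minimum(moca + 1, 30), moca)
    adj[~(np.isfinite(moca) & np.isfinite(edu))] = np.nan
    out["moca_adjusted"] = adj
    return out
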