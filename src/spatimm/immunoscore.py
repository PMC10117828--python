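"""Percentile-based Immunoscore.

The Immunoscore summarizes T-cell infiltration from CD3+ and CD8+ cell
densities in the tumor core and invasive margin.  Each of the four density
columns is converted to within-cohort percentiles; a patient's score is the
arithmetic mean of their four percentiles, and the two-category call is
low (score <= 25) versus high (score > 25), the boundary being inclusive on
the low side.

The percentile definition is ``100 * rank / n`` with mid-rank ties (the
cohort maximum maps to 100); the alternative ``100 * (rank - 0.5) / n``
convention is available via ``method="midrank"``.  Because the score is a
pure rank statistic it is invariant to any cohort-wide monotone rescaling
of the densities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "IMMUNOSCORE_COLUMNS",
    "ImmunoscoreResult",
    "percentile_rank",
    "immunoscore",
    "cohort_immunoscore",
]

IMMUNOSCORE_COLUMNS = ("TC-CD3", "IM-CD3", "TC-CD8", "IM-CD8")
LOW_BOUNDARY = 25.0


def percentile_rank(values: np.ndarray, method: str = "rank") -> np.ndarray:
    """Within-cohort percentiles of a density column.

    ``method="rank"`` (default): 100 * rank / n; ``method="midrank"``:
    100 * (rank - 0.5) / n.  Ties get their mid-rank in both cases.
    NaNs propagate.  Requires at least two non-missing patients.
    """
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    if ok.sum() < 2:
        raise ValueError("at least two non-missing values are required")
    ranks = rankdata(v[ok], method="average")
    n = ok.sum()
    if method == "rank":
        pct = 100.0 * ranks / n
    elif method == "midrank":
        pct = 100.0 * (ranks - 0.5) / n
    else:
        raise ValueError(f"unknown percentile method {method!r}")
    out = np.full_like(v, np.nan)
    out[ok] = pct
    return out


@dataclass(frozen=True)
class ImmunoscoreResult:
    score: float
    category: str  # "low" (score <= 25) or "high"


def immunoscore(percentiles: np.ndarray, boundary: float = LOW_BOUNDARY) -> ImmunoscoreResult:
    """Mean of the four percentiles; low iff score <= boundary."""
    p = np.asarray(percentiles, dtype=float)
    if p.shape != (4,) or not np.all(np.isfinite(p)):
        raise ValueError("exactly four finite percentiles are required")
    score = float(p.mean())
    return ImmunoscoreResult(score, "low" if score <= boundary else "high")


def cohort_immunoscore(
    densities: pd.DataFrame,
    boundary: float = LOW_BOUNDARY,
    method: str = "rank",
) -> pd.DataFrame:
    """Immunoscore for every patient of a cohort.

    ``densities`` must contain the four columns TC-CD3, IM-CD3, TC-CD8,
    IM-CD8 (cells/mm²).  Patients with any missing component get a missing
    score, flagged by ``category="missing"``.
    """
    missing = [c for c in IMMUNOSCORE_COLUMNS if c not in densities.columns]
    if missing:
        raise ValueError(f"missing Immunoscore density columns: {missing}")
    pct = pd.DataFrame(
        {c: percentile_rank(densities[c].to_numpy(), method=method) for c in IMMUNOSCORE_COLUMNS},
        index=densities.index,
    )
    score = pct.mean(axis=1, skipna=False)
    category = pd.Series(
        np.where(score.isna(), "missing", np.where(score <= boundary, "low", "high")),
        index=densities.index,
    )
    return pd.DataFrame({"Immunoscore": score, "Immunoscore_category": category})
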