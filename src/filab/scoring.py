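"""FI-Lab scoring: deficit dichotomization, completeness rule, quartiles.

Each of the 33 registry items is dichotomized against its reference
interval — any value outside the normal range scores 1 (a deficit),
anything within (bounds included) scores 0, and a missing measurement is
ignored. The FI-Lab score is the number of deficits divided by the number
of items actually measured, so it lies in [0, 1]. A record must carry more
than 80% of the panel (>= 27 of 33 items) for its score to be defined;
sparser records are flagged for exclusion. Quartile categories are
assigned cohort-wide from the empirical score distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .registry import ReferenceItem, ReferenceRegistry

#: prefix of per-item columns in a cohort table (avoids clashing with the
#: troponin-T covariate column, which is a separate model term)
ITEM_PREFIX = "item_"

#: minimum measured items for a defined score: more than 80% of 33
DEFAULT_MIN_ITEMS = 27

MISSING = None

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


@dataclass(frozen=True)
class FILabResult:
    """Scoring outcome for one ICU stay.

    ``score`` is ``None`` (undefined) when fewer than the required number
    of items were measured; ``quartile`` is assigned cohort-wide, not here.
    """

    n_available: int
    n_deficits: int
    score: Optional[float]
    quartile: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.score is not None


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return False


def is_deficit(item: ReferenceItem, value):
    """Dichotomize one measurement: 1 deficit, 0 normal, None missing.

    Continuous values strictly beyond a reference bound are deficits; the
    bounds themselves are normal. Dipstick readings other than the item's
    normal category are deficits. Raises ``TypeError`` for a non-numeric
    value on a continuous item.
    """
    if _is_missing(value):
        return MISSING
    if item.value_kind == "continuous":
        try:
            v = float(value)
        except (TypeError, ValueError):
            raise TypeError(f"item {item.name!r}: non-numeric value {value!r}") from None
        if item.lower is not None and v < item.lower:
            return 1
        if item.upper is not None and v > item.upper:
            return 1
        return 0
    return 0 if str(value) == item.normal_category else 1


def score_filab(
    items: Mapping[str, object],
    registry: ReferenceRegistry,
    min_items: int = DEFAULT_MIN_ITEMS,
) -> FILabResult:
    """Score one record's item mapping (registry name -> value or missing)."""
    extra = set(items) - set(registry.names)
    absent = set(registry.names) - set(items)
    if extra or absent:
        raise KeyError(
            f"item keys do not match registry: unexpected={sorted(extra)}, absent={sorted(absent)}"
        )
    n_avail = 0
    n_def = 0
    for it in registry:
        d = is_deficit(it, items[it.name])
        if d is MISSING:
            continue
        n_avail += 1
        n_def += d
    score = n_def / n_avail if n_avail >= min_items else None
    return FILabResult(n_available=n_avail, n_deficits=n_def, score=score)


def deficit_table(cohort: pd.DataFrame, registry: ReferenceRegistry) -> pd.DataFrame:
    """Per-item deficit indicators (0/1, NaN when missing) for a cohort table.

    Item values are read from ``item_<name>`` columns; dipstick items may be
    any string category, continuous items must be numeric.
    """
    out = {}
    for it in registry:
        col = ITEM_PREFIX + it.name
        if col not in cohort.columns:
            raise KeyError(f"cohort is missing item column {col!r}")
        s = cohort[col]
        if it.value_kind == "continuous":
            v = pd.to_numeric(s, errors="raise").astype(float)
            d = pd.Series(np.zeros(len(v)), index=cohort.index)
            if it.lower is not None:
                d[v < it.lower] = 1.0
            if it.upper is not None:
                d[v > it.upper] = 1.0
            d[v.isna()] = np.nan
        else:
            miss = s.isna()
            d = pd.Series(np.nan, index=cohort.index)
            d[~miss] = (s[~miss].astype(str) != it.normal_category).astype(float)
        out[it.name] = d
    return pd.DataFrame(out, index=cohort.index)


def score_table(
    cohort: pd.DataFrame,
    registry: ReferenceRegistry,
    min_items: int = DEFAULT_MIN_ITEMS,
    assign_quartile: bool = True,
) -> pd.DataFrame:
    """Vectorized scoring: returns the cohort with fi_lab_* columns appended.

    Adds ``fi_lab_n_available``, ``fi_lab_n_deficits``, ``fi_lab_score``
    (NaN when undefined under the completeness rule) and, when requested,
    ``fi_lab_quartile`` computed over the defined scores.
    """
    d = deficit_table(cohort, registry)
    n_avail = d.notna().sum(axis=1)
    n_def = d.sum(axis=1, skipna=True)
    score = n_def / n_avail
    score[n_avail < min_items] = np.nan
    out = cohort.copy()
    out["fi_lab_n_available"] = n_avail.astype(int)
    out["fi_lab_n_deficits"] = n_def.astype(int)
    out["fi_lab_score"] = score
    if assign_quartile:
        q = pd.Series(pd.NA, index=out.index, dtype="string")
        defined = score.notna()
        if defined.any():
            q[defined] = assign_quartiles(score[defined].to_numpy())
        out["fi_lab_quartile"] = q
    return out


def assign_quartiles(scores: Sequence[float]) -> np.ndarray:
    """Quartile categories Q1-Q4 from the empirical 25/50/75 percentiles.

    Intervals are left-open/right-closed except Q1, which includes the
    minimum; a score tied with a cut point goes to the lower quartile.
    Degenerate inputs (fewer than 4 distinct values) trigger a warning but
    are still categorized.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot assign quartiles to an empty score collection")
    if np.isnan(arr).any():
        raise ValueError("all scores must be defined (non-NaN) for quartile assignment")
    if len(np.unique(arr)) < 4:
        warnings.warn(
            "fewer than 4 distinct scores: quartile categorization is degenerate",
            UserWarning,
            stacklevel=2,
        )
    cuts = np.quantile(arr, [0.25, 0.50, 0.75])
    # searchsorted(left): a score equal to a cut point stays below it
    idx = np.searchsorted(cuts, arr, side="left")
    return np.asarray(QUARTILE_LABELS, dtype=object)[idx]
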