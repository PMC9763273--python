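"""Published summary counts from a critical-AMI ICU cohort (n = 2,159).

These are aggregate counts reported for a real first-ICU-stay acute
myocardial infarction cohort stratified by FI-Lab quartile. The
individual-level data are access-restricted, but the quartile sizes and
death counts are enough to recompute the crude (unadjusted) quartile odds
ratios and the marginal mortality proportions, which serve as a fixed
external cross-check of the 2x2 odds-ratio and crude-logistic machinery.
"""

from __future__ import annotations

import pandas as pd

from .association import ContingencyTable2x2, or_from_2x2
from .scoring import QUARTILE_LABELS

#: patients per FI-Lab quartile, Q1..Q4
QUARTILE_N = (542, 585, 543, 489)
#: in-hospital deaths per quartile
INHOSPITAL_DEATHS = (31, 79, 142, 225)
#: 1-year deaths per quartile (in-hospital deaths included)
ONE_YEAR_DEATHS = (112, 214, 262, 310)

TOTAL_N = sum(QUARTILE_N)  # 2159
TOTAL_INHOSPITAL_DEATHS = sum(INHOSPITAL_DEATHS)  # 477
TOTAL_ONE_YEAR_DEATHS = sum(ONE_YEAR_DEATHS)  # 898


def quartile_2x2(quartile: str, deaths=INHOSPITAL_DEATHS) -> ContingencyTable2x2:
    """2x2 table of the given quartile's deaths against Q1 (reference)."""
    idx = QUARTILE_LABELS.index(quartile)
    if idx == 0:
        raise ValueError("Q1 is the reference category")
    a, c = deaths[idx], deaths[0]
    b, d = QUARTILE_N[idx] - a, QUARTILE_N[0] - c
    return ContingencyTable2x2(a, b, c, d)


def crude_quartile_ors() -> pd.DataFrame:
    """Crude quartile odds ratios vs Q1 recomputed from the published counts."""
    rows = []
    for outcome, deaths in (
        ("death_inhospital", INHOSPITAL_DEATHS),
        ("death_1yr", ONE_YEAR_DEATHS),
    ):
        for q in QUARTILE_LABELS[1:]:
            r = or_from_2x2(quartile_2x2(q, deaths))
            rows.append(
                {"outcome": outcome, "quartile": q, "OR": r.odds_ratio,
                 "CI_low": r.ci_low, "CI_high": r.ci_high}
            )
    return pd.DataFrame(rows)


def expand_counts_to_records(deaths=INHOSPITAL_DEATHS) -> pd.DataFrame:
    """Individual-level expansion (quartile, death) of the published counts.

    Lets the crude quartile logistic model be refit directly, which must
    reproduce the 2x2 cross-product odds ratios exactly.
    """
    rows = []
    for q, n, d in zip(QUARTILE_LABELS, QUARTILE_N, deaths):
        rows.extend({"fi_lab_quartile": q, "death": 1} for _ in range(d))
        rows.extend({"fi_lab_quartile": q, "death": 0} for _ in range(n - d))
    return pd.DataFrame(rows)


def mortality_proportions() -> dict[str, float]:
    """Marginal mortality percentages implied by the published counts."""
    return {
        "inhospital_pct": 100.0 * TOTAL_INHOSPITAL_DEATHS / TOTAL_N,
        "one_year_pct": 100.0 * TOTAL_ONE_YEAR_DEATHS / TOTAL_N,
        "q4_inhospital_pct": 100.0 * INHOSPITAL_DEATHS[3] / QUARTILE_N[3],
    }
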