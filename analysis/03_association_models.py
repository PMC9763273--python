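#!/usr/bin/env python
"""Association of the FI-Lab with in-hospital and 1-year mortality.

Quartile-stratified descriptives, crude / age-sex / fully adjusted
logistic odds ratios for the FI-Lab as a continuous (per 0.01) and
quartile exposure with trend tests, the adjusted spline dose-response
curve, and the per-item univariate screens.
"""

from pathlib import Path

import pandas as pd

from filab import default_registry
from filab.association import (
    MODEL1_ADJUST,
    MODEL2_ADJUST,
    ModelSpec,
    describe_by_group,
    fit_logistic,
    per_item_screen,
    rcs_dose_response,
    trend_test,
)
from filab.pipeline import load_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = load_cohort(RESULTS / "cohort_scored.csv")
    registry = default_registry()

    describe_by_group(cohort).to_csv(RESULTS / "table1_descriptives.csv", index=False)

    rows = []
    for outcome in ("death_inhospital", "death_1yr"):
        for label, adj in (("crude", ()), ("model1", MODEL1_ADJUST), ("model2", MODEL2_ADJUST)):
            cont = fit_logistic(cohort, ModelSpec(outcome, "filab_per001", adj))
            quart = fit_logistic(cohort, ModelSpec(outcome, "filab_quartile", adj))
            p_trend = trend_test(cohort, ModelSpec(outcome, adjustment_set=adj))
            for fit in (cont, quart):
                for _, r in fit.or_table.iterrows():
                    if r["term"].startswith("filab"):
                        rows.append({"outcome": outcome, "model": label, **r})
            rows.append({"outcome": outcome, "model": label, "term": "p_for_trend", "p": p_trend})
    or_table = pd.DataFrame(rows)
    or_table.to_csv(RESULTS / "table3_filab_or.csv", index=False)

    rcs_dose_response(cohort).to_csv(RESULTS / "figure1_spline.csv", index=False)
    per_item_screen(cohort, registry=registry).to_csv(
        RESULTS / "per_item_screen.csv", index=False
    )

    show = or_table[or_table["outcome"] == "death_inhospital"]
    print("FI-Lab association with in-hospital mortality (OR, 95% CI):")
    for _, r in show.iterrows():
        if r["term"] == "p_for_trend":
            print(f"  {r['model']:>6}  p for trend = {r['p']:.2e}")
        else:
            print(f"  {r['model']:>6}  {r['term']:<14} "
                  f"{r['OR']:.2f} ({r['CI_low']:.2f}-{r['CI_high']:.2f})")
    print(f"\nwrote table1/table3/spline/per-item tables under {RESULTS}")


if __name__ == "__main__":
    main()
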