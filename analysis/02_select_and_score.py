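#!/usr/bin/env python
"""Apply the cohort-selection filters and score the FI-Lab.

Selection: AMI diagnosis codes, age >= 18, survival >= 24 h, complete key
covariates and severity scores, >= 27 of 33 measured items, first ICU
stay. Scoring: deficits / measured items, with cohort-wide quartiles.
"""

from pathlib import Path

from filab import default_registry, select_ami_cohort, score_table
from filab.pipeline import load_cohort, save_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    registry = default_registry()
    raw = load_cohort(RESULTS / "cohort_raw.csv")
    selected, excl = select_ami_cohort(raw, registry=registry)
    excl.to_csv(RESULTS / "exclusion_log.tsv", sep="\t", index=False)

    scored = score_table(selected, registry)
    defined = scored[scored["fi_lab_score"].notna()].reset_index(drop=True)
    save_cohort(defined, RESULTS / "cohort_scored.csv")

    print(f"selection: {len(raw)} -> {len(selected)} records")
    print(excl.to_string(index=False))
    q = defined["fi_lab_score"].quantile([0.25, 0.5, 0.75])
    print(f"\nFI-Lab median (IQR): {q[0.5]:.2f} ({q[0.25]:.2f}-{q[0.75]:.2f})")
    print("quartile sizes:", defined["fi_lab_quartile"].value_counts().sort_index().to_dict())
    print(f"wrote {RESULTS / 'cohort_scored.csv'}")


if __name__ == "__main__":
    main()
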