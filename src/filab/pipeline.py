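"""End-to-end pipeline: generate/load -> select -> score -> model -> report.

One configured, seeded run produces analogues of the analysis tables:
quartile descriptives, covariate associations, FI-Lab odds ratios (crude /
age-sex / fully adjusted), the incremental-value table over the six
severity scores, the spline dose-response curve, the exclusion log, and a
JSON manifest (config hash, registry checksum, seed, row counts per stage)
that fully identifies the run. Reruns with the same inputs are
byte-identical; any stage failure aborts the run and removes partial
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .association import (
    MODEL1_ADJUST,
    MODEL2_ADJUST,
    ModelSpec,
    describe_by_group,
    fit_logistic,
    per_item_screen,
    rcs_dose_response,
    trend_test,
)
from .cohort import SEVERITY_SCORES, CohortConfig, generate_cohort, select_ami_cohort
from .incremental import incremental_table
from .registry import ReferenceRegistry, default_registry
from .scoring import DEFAULT_MIN_ITEMS, ITEM_PREFIX, score_table

log = logging.getLogger("filab.pipeline")

ARTIFACTS = (
    "cohort_scored.csv",
    "table1_descriptives.csv",
    "table2_covariates.csv",
    "table3_filab_or.csv",
    "table4_incremental.csv",
    "figure1_spline.csv",
    "exclusion_log.tsv",
)


@dataclass
class RunConfig:
    """Everything that determines one pipeline run."""

    outputs_dir: Path
    seed: int = 0
    cohort_file: Optional[Path] = None  # None: generate synthetically
    cohort: CohortConfig = field(default_factory=CohortConfig)
    registry_path: Optional[Path] = None  # None: shipped default registry
    min_items: int = DEFAULT_MIN_ITEMS
    base_scores: tuple[str, ...] = SEVERITY_SCORES
    outcomes: tuple[str, ...] = ("death_inhospital", "death_1yr")
    report_rounding_or: int = 2
    report_rounding_improvement: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        for key in ("outputs_dir", "cohort_file", "registry_path"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        for key in ("base_scores", "outcomes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(cohort=cohort, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed,
                "cohort_file": str(self.cohort_file) if self.cohort_file else None,
                "cohort": vars(self.cohort) | {"covariate_effects": dict(self.cohort.covariate_effects),
                                               "outcome_intercepts": list(self.cohort.outcome_intercepts)},
                "min_items": self.min_items,
                "base_scores": list(self.base_scores),
                "outcomes": list(self.outcomes),
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def validate_inputs(
    cohort: pd.DataFrame | str | Path, registry: Optional[ReferenceRegistry] = None
) -> pd.DataFrame:
    """Schema and range diagnostics for a cohort table, without mutating it.

    Returns one row per violation (check, column, row id or count,
    message); an empty frame means the table is clean.
    """
    registry = registry or default_registry()
    if not isinstance(cohort, pd.DataFrame):
        cohort = load_cohort(cohort)
    problems = []

    def add(check, column, where, message):
        problems.append({"check": check, "column": column, "where": where, "message": message})

    required = [
        "patient_id", "age", "gender", "ethnicity", "ami_type", "troponin_t",
        *SEVERITY_SCORES, "death_inhospital", "death_1yr",
    ] + [ITEM_PREFIX + n for n in registry.names]
    for col in required:
        if col not in cohort.columns:
            add("schema", col, "", "required column absent")
    if problems:
        return pd.DataFrame(problems)

    neg_trop = cohort.index[pd.to_numeric(cohort["troponin_t"]) < 0]
    for i in neg_trop:
        add("range", "troponin_t", str(cohort.loc[i, "patient_id"]), "negative troponin")
    under_age = cohort.index[pd.to_numeric(cohort["age"]) < 0]
    for i in under_age:
        add("range", "age", str(cohort.loc[i, "patient_id"]), "negative age")
    from .cohort import SEVERITY_RANGES

    for name in SEVERITY_SCORES:
        v = pd.to_numeric(cohort[name])
        lo, hi = SEVERITY_RANGES[name]
        bad = cohort.index[(v < lo) | (v > hi)]
        for i in bad:
            add("range", name, str(cohort.loc[i, "patient_id"]),
                f"outside admissible range [{lo}, {hi}]")
    for col in ("death_inhospital", "death_1yr"):
        v = pd.to_numeric(cohort[col])
        if not set(v.dropna().unique()) <= {0, 1}:
            add("range", col, "", "outcome must be 0/1")
    nested = pd.to_numeric(cohort["death_inhospital"]) <= pd.to_numeric(cohort["death_1yr"])
    for i in cohort.index[~nested.fillna(True)]:
        add("consistency", "death_1yr", str(cohort.loc[i, "patient_id"]),
            "in-hospital death not counted as 1-year death")
    return pd.DataFrame(problems, columns=["check", "column", "where", "message"])


def save_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """CSV serialization; missing item values become empty cells."""
    cohort.to_csv(path, index=False)


def load_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "icd_codes": str})
    return df


def run_pipeline(config: RunConfig, registry: Optional[ReferenceRegistry] = None) -> dict:
    """Execute all stages in order; return the run manifest (also written).

    Stages: cohort acquisition, selection, FI-Lab scoring + quartiles,
    descriptives, association models, spline curve, per-item screens,
    incremental value. Any failure removes files written so far and raises
    :class:`PipelineError` naming the stage.
    """
    registry = registry or (
        ReferenceRegistry.load(config.registry_path) if config.registry_path else default_registry()
    )
    out = Path(config.outputs_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "config_hash": config.config_hash(),
        "registry_checksum": registry.checksum(),
        "seed": config.seed,
        "package_version": __version__,
        "min_items": config.min_items,
        "stages": {},
    }

    def emit(name: str, frame: pd.DataFrame, sep: str = ",") -> None:
        path = out / name
        frame.to_csv(path, index=False, sep=sep)
        written.append(path)

    def stage(name: str, n_in: int, n_out: int, t0: float) -> None:
        manifest["stages"][name] = {"n_in": n_in, "n_out": n_out}
        log.info("stage=%s n_in=%d n_out=%d wall=%.2fs", name, n_in, n_out, time.time() - t0)

    try:
        t0 = time.time()
        if config.cohort_file is not None:
            raw = load_cohort(config.cohort_file)
        else:
            cc = config.cohort
            if cc.seed != config.seed:
                cc = CohortConfig(**{**vars(cc), "seed": config.seed})
            raw = generate_cohort(cc, registry)
        stage("acquire", len(raw), len(raw), t0)

        t0 = time.time()
        selected, excl_log = select_ami_cohort(raw, config.min_items, registry)
        emit("exclusion_log.tsv", excl_log, sep="\t")
        if len(selected) == 0:
            raise PipelineError(
                "select", "no records survive selection (check min_items and filters)"
            )
        stage("select", len(raw), len(selected), t0)

        t0 = time.time()
        scored = score_table(selected, registry, config.min_items)
        defined = scored[scored["fi_lab_score"].notna()].reset_index(drop=True)
        if len(defined) == 0:
            raise PipelineError("score", "no record has a defined FI-Lab score")
        emit("cohort_scored.csv", defined)
        stage("score", len(selected), len(defined), t0)

        t0 = time.time()
        emit("table1_descriptives.csv", describe_by_group(defined))
        stage("describe", len(defined), len(defined), t0)

        t0 = time.time()
        cov_rows, filab_rows = [], []
        for outcome in config.outcomes:
            # covariate associations, univariate and fully adjusted
            uni_terms = ["age", "gender", "ethnicity", "ami_type", "troponin_t",
                         "filab_per001", *config.base_scores]
            for term in uni_terms:
                f = fit_logistic(defined, ModelSpec(outcome, exposure=term, age_per5=True))
                for _, r in f.or_table.iterrows():
                    cov_rows.append({"outcome": outcome, "model": "univariate", **r})
            multi = fit_logistic(
                defined,
                ModelSpec(outcome, exposure="filab_per001", adjustment_set=MODEL2_ADJUST,
                          age_per5=True),
            )
            for _, r in multi.or_table.iterrows():
                cov_rows.append({"outcome": outcome, "model": "multivariable", **r})
            # FI-Lab models: crude / model 1 / model 2, continuous and quartile
            for label, adj in (("crude", ()), ("model1", MODEL1_ADJUST), ("model2", MODEL2_ADJUST)):
                for expo in ("filab_per001", "filab_quartile"):
                    f = fit_logistic(defined, ModelSpec(outcome, exposure=expo, adjustment_set=adj))
                    for _, r in f.or_table.iterrows():
                        if r["term"].startswith("filab"):
                            filab_rows.append(
                                {"outcome": outcome, "model": label, "n_used": f.n_used, **r}
                            )
                p_trend = trend_test(defined, ModelSpec(outcome, adjustment_set=adj))
                filab_rows.append(
                    {"outcome": outcome, "model": label, "term": "p_for_trend",
                     "estimate": float("nan"), "OR": float("nan"), "CI_low": float("nan"),
                     "CI_high": float("nan"), "p": p_trend, "n_used": len(defined)}
                )
        emit("table2_covariates.csv", pd.DataFrame(cov_rows))
        emit("table3_filab_or.csv", pd.DataFrame(filab_rows))
        stage("associate", len(defined), len(defined), t0)

        t0 = time.time()
        emit("figure1_spline.csv", rcs_dose_response(defined))
        emit("per_item_screen.csv", per_item_screen(defined, registry=registry))
        stage("spline_and_screen", len(defined), len(defined), t0)

        t0 = time.time()
        emit(
            "table4_incremental.csv",
            incremental_table(defined, config.base_scores, config.outcomes),
        )
        stage("incremental", len(defined), len(defined), t0)

        manifest["artifacts"] = sorted(p.name for p in written)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest
    except PipelineError:
        _cleanup(written)
        raise
    except Exception as exc:  # attribute the failure to a stage for the operator
        _cleanup(written)
        done = list(manifest["stages"])
        current = done[-1] if done else "acquire"
        raise PipelineError(f"after:{current}", str(exc)) from exc


def _cleanup(paths: Sequence[Path]) -> None:
    for p in paths:
        try:
            p.unlink(missing_ok=True)
        except OSError:
            pass
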