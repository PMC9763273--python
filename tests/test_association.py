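import numpy as np
import pandas as pd
import pytest
from scipy import stats

from filab.association import (
    ContingencyTable2x2,
    ModelSpec,
    describe_by_group,
    fit_logistic,
    or_from_2x2,
    per_item_screen,
    rcs_basis,
    rcs_dose_response,
    trend_test,
)
from filab.cohort import CohortConfig, generate_cohort
from filab.scoring import score_table
from filab import published


class TestOrFrom2x2:
    @pytest.mark.parametrize(
        "cells,expected_or,expected_ci",
        [
            # quartile deaths vs Q1 from the published cohort counts
            ((79, 506, 31, 511), 2.57, (1.67, 3.97)),
            ((142, 401, 31, 511), 5.84, None),
            ((225, 264, 31, 511), 14.05, (9.38, 21.04)),
            ((262, 281, 112, 430), 3.58, None),
            ((310, 179, 112, 430), 6.65, None),
        ],
    )
    def test_reproduces_published_crude_quartile_ors(self, cells, expected_or, expected_ci):
        res = or_from_2x2(ContingencyTable2x2(*cells))
        assert round(res.odds_ratio, 2) == expected_or
        if expected_ci:
            assert (round(res.ci_low, 2), round(res.ci_high, 2)) == expected_ci

    def test_symmetric_table_gives_unit_or(self):
        res = or_from_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_zero_cell_uses_haldane_correction_and_flags(self):
        res = or_from_2x2(ContingencyTable2x2(5, 0, 3, 7))
        assert res.corrected
        assert np.isfinite(res.odds_ratio)
        assert res.odds_ratio == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


def _brute_force_kruskal(groups):
    """Rank-sum Kruskal-Wallis H with tie correction, computed from scratch."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    h, start = 0.0, 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


class TestDescribeByGroup:
    def test_kruskal_matches_hand_computed_statistic(self):
        groups = [np.array([1.0, 3.0, 5.0, 7.0]), np.array([2.0, 4.0, 6.0]),
                  np.array([8.0, 9.0, 10.0, 11.0])]
        h_oracle = _brute_force_kruskal(groups)
        h_scipy, _ = stats.kruskal(*groups)
        assert h_scipy == pytest.approx(h_oracle)

    def test_identical_groups_give_null_pvalues(self, registry):
        cfg = CohortConfig(n_patients=120, seed=9)
        cohort = score_table(generate_cohort(cfg, registry), registry)
        # duplicate every record across two fake quartiles: no group signal
        dup = pd.concat([cohort.assign(fi_lab_quartile="Q1"),
                         cohort.assign(fi_lab_quartile="Q2")], ignore_index=True)
        table = describe_by_group(dup)
        assert (table["p"] > 0.99).all()

    def test_published_death_counts_give_significant_chi2(self):
        deaths = published.INHOSPITAL_DEATHS
        ns = published.QUARTILE_N
        table = np.array([deaths, [n - d for n, d in zip(ns, deaths)]])
        _, p, _, _ = stats.chi2_contingency(table)
        assert p < 0.001

    def test_layout_has_group_columns_and_p(self, scored_cohort):
        table = describe_by_group(scored_cohort)
        for col in ("variable", "Q1", "Q2", "Q3", "Q4", "p"):
            assert col in table.columns
        assert set(table["variable"]) >= {"age", "fi_lab_score", "sofa", "death_inhospital"}


class TestFitLogistic:
    def test_binary_predictor_matches_2x2_cross_product(self):
        # crude logistic OR for one binary exposure is an algebraic identity
        # with the contingency-table cross-product ratio
        records = published.expand_counts_to_records()
        records = records[records["fi_lab_quartile"].isin(["Q1", "Q4"])].copy()
        records["death_inhospital"] = records.pop("death")
        records["q4"] = (records["fi_lab_quartile"] == "Q4").astype(float)
        fit = fit_logistic(records, ModelSpec("death_inhospital", exposure="q4"))
        or_q4 = fit.odds_ratio("q4")[0]
        oracle = or_from_2x2(published.quartile_2x2("Q4")).odds_ratio
        assert or_q4 == pytest.approx(oracle, rel=1e-6)

    def test_wald_ci_log_symmetric_about_or(self, scored_cohort):
        fit = fit_logistic(scored_cohort, ModelSpec("death_inhospital"))
        row = fit.or_table.set_index("term").loc["filab_per001"]
        assert np.log(row.OR) - np.log(row.CI_low) == pytest.approx(
            np.log(row.CI_high) - np.log(row.OR)
        )

    def test_complete_case_dropping_is_logged(self, scored_cohort):
        holed = scored_cohort.copy()
        holed.loc[holed.index[:25], "troponin_t"] = np.nan
        base = fit_logistic(holed, ModelSpec("death_inhospital"))
        adj = fit_logistic(
            holed, ModelSpec("death_inhospital", adjustment_set=("troponin_t",))
        )
        assert base.n_dropped == 0
        assert adj.n_dropped == 25
        assert adj.n_used == base.n_used - 25

    def test_single_class_outcome_rejected(self, scored_cohort):
        dead = scored_cohort[scored_cohort["death_inhospital"] == 1]
        with pytest.raises(ValueError):
            fit_logistic(dead, ModelSpec("death_inhospital"))

    def test_separation_is_flagged_not_silent(self):
        n = 60
        df = pd.DataFrame({
            "death_inhospital": np.repeat([0, 1], n // 2),
            "fi_lab_score": np.repeat([0.1, 0.9], n // 2),
        })
        fit = fit_logistic(df, ModelSpec("death_inhospital"))
        assert not fit.converged

    def test_quartile_ors_monotone_under_monotone_generation(self, scored_cohort):
        fit = fit_logistic(
            scored_cohort, ModelSpec("death_inhospital", exposure="filab_quartile")
        )
        ors = [fit.odds_ratio(f"filab_Q{k}")[0] for k in (2, 3, 4)]
        assert ors[0] < ors[1] < ors[2]


class TestTrendTest:
    def test_two_level_quartiles_equal_binary_wald_test(self, scored_cohort):
        two = scored_cohort.copy()
        two["fi_lab_quartile"] = np.where(
            two["fi_lab_score"] > two["fi_lab_score"].median(), "Q2", "Q1"
        )
        p_trend = trend_test(two, ModelSpec("death_inhospital"))
        binary = two.assign(high=(two["fi_lab_quartile"] == "Q2").astype(float))
        fit = fit_logistic(binary, ModelSpec("death_inhospital", exposure="high"))
        assert p_trend == pytest.approx(fit.p_value("high"), rel=1e-6)

    def test_strong_monotone_signal_significant(self, scored_cohort):
        assert trend_test(scored_cohort, ModelSpec("death_inhospital")) < 0.001


class TestSpline:
    def test_basis_linear_in_tails(self):
        knots = [0.2, 0.5, 0.8]
        x = np.array([-0.5, 0.0, 0.1, 0.9, 1.0, 1.5])
        b = rcs_basis(x, knots)
        below = b[x < knots[0], 1]
        assert np.allclose(below, 0.0)  # cubic term vanishes left of first knot
        # second differences of the nonlinear term vanish beyond the last knot
        xs = np.array([1.0, 1.5, 2.0, 2.5])
        tail = rcs_basis(xs, knots)[:, 1]
        assert np.allclose(np.diff(tail, 2), 0.0, atol=1e-10)

    def test_or_at_reference_is_one_and_grid_spans_range(self, scored_cohort):
        # pin the reference to a grid point (the minimum) for an exact check
        ref = float(scored_cohort["fi_lab_score"].min())
        curve = rcs_dose_response(scored_cohort, reference=ref, n_grid=51)
        assert curve["odds_ratio"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert curve["fi_lab_score"].iloc[0] == pytest.approx(scored_cohort["fi_lab_score"].min())
        assert curve["fi_lab_score"].iloc[-1] == pytest.approx(scored_cohort["fi_lab_score"].max())
        # default reference: cohort 25th percentile, OR ~1 by interpolation
        default_curve = rcs_dose_response(scored_cohort, n_grid=201)
        q25 = float(scored_cohort["fi_lab_score"].quantile(0.25))
        near = np.interp(q25, default_curve["fi_lab_score"], np.log(default_curve["odds_ratio"]))
        assert near == pytest.approx(0.0, abs=5e-3)

    def test_reference_outside_range_rejected(self, scored_cohort):
        with pytest.raises(ValueError):
            rcs_dose_response(scored_cohort, reference=2.0)

    def test_linear_truth_within_band_of_straight_line(self, registry, rng):
        # outcome generated with log-odds linear in the FI-Lab: the fitted
        # spline curve must cover the true line over the central range
        n = 4000
        score = rng.uniform(0.1, 0.8, n)
        beta = 4.0
        p = 1 / (1 + np.exp(-(-2.5 + beta * score)))
        df = pd.DataFrame({
            "fi_lab_score": score,
            "death_inhospital": (rng.random(n) < p).astype(int),
        })
        ref = float(np.quantile(score, 0.25))
        curve = rcs_dose_response(df, adjustment_set=(), reference=ref, n_grid=41)
        inner = curve[(curve["fi_lab_score"] > 0.15) & (curve["fi_lab_score"] < 0.75)]
        truth = np.exp(beta * (inner["fi_lab_score"] - ref))
        assert ((inner["ci_low"] <= truth) & (truth <= inner["ci_high"])).mean() > 0.9


class TestPerItemScreen:
    def test_null_item_or_near_one_c_near_half(self, rng):
        n = 4000
        d = rng.random(n) < 0.4
        y = rng.random(n) < 0.3  # independent of the deficit
        from filab.association import ContingencyTable2x2, or_from_2x2
        from filab.incremental import c_statistic

        a = int((d & y).sum()); b = int((d & ~y).sum())
        c = int((~d & y).sum()); dd = int((~d & ~y).sum())
        res = or_from_2x2(ContingencyTable2x2(a, b, c, dd))
        cstat, _ = c_statistic(d.astype(float), y.astype(int))
        assert res.odds_ratio == pytest.approx(1.0, abs=0.2)
        assert cstat == pytest.approx(0.5, abs=0.03)

    def test_binary_c_statistic_equals_closed_form(self, scored_cohort, registry):
        table = per_item_screen(scored_cohort, registry=registry)
        from filab.scoring import deficit_table

        defs = deficit_table(scored_cohort, registry)
        y = scored_cohort["death_inhospital"]
        for _, row in table.dropna(subset=["c_statistic"]).head(8).iterrows():
            d = defs[row["item"]]
            mask = d.notna()
            sens = ((d[mask] == 1) & (y[mask] == 1)).sum() / (y[mask] == 1).sum()
            spec = ((d[mask] == 0) & (y[mask] == 0)).sum() / (y[mask] == 0).sum()
            assert row["c_statistic"] == pytest.approx((sens + spec) / 2, abs=1e-10)

    def test_perfect_predictor_c_is_one(self):
        y = np.array([0] * 10 + [1] * 10)
        from filab.incremental import c_statistic

        c, _ = c_statistic(y.astype(float), y)
        assert c == 1.0

    def test_screen_covers_all_items_and_flags_degenerate(self, scored_cohort, registry):
        zeroed = scored_cohort.copy()
        zeroed["item_sodium"] = 140.0  # no variance in the deficit
        table = per_item_screen(zeroed, registry=registry)
        assert len(table) == 33
        assert table.set_index("item").loc["sodium", "flag"] == "zero_variance"
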