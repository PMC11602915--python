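"""Gaps, quadrant performance classes, context correlations, tidy exports."""

import numpy as np
import pandas as pd
import pytest

from urbanpoverty import (
    PerformanceRule,
    classify_performance,
    context_correlations,
    export_tidy_outputs,
    group_prevalences,
    performance_table,
)
from urbanpoverty.outcomes import outcome_table

from conftest import loop_weighted_prevalence


class TestGroupPrevalences:
    def test_gap_sign_convention(self):
        hh = pd.DataFrame({"household_id": [f"h{i}" for i in range(10)],
                           "city_id": "c1", "weight": np.ones(10)})
        poor = np.array([1] * 5 + [0] * 5, float)
        outcomes = pd.DataFrame({"no_electricity": [1, 1, 1, 1, 1, 1, 0, 0, 0, 0.0]})
        out = group_prevalences(hh, poor, outcomes)
        row = out.iloc[0]
        assert row["prev_poor"] == pytest.approx(1.0)
        assert row["prev_rich"] == pytest.approx(0.2)
        assert row["gap"] == pytest.approx(-0.8)

    def test_identical_groups_zero_gap(self):
        hh = pd.DataFrame({"household_id": ["a", "b"], "city_id": "c1", "weight": [1.0, 1.0]})
        out = group_prevalences(hh, [1.0, 0.0], pd.DataFrame({"x": [1.0, 1.0]}))
        assert out["gap"].iloc[0] == 0.0

    def test_matches_loop_oracle(self, one_city):
        ds, _ = one_city
        hh = ds.households
        outcomes = outcome_table(hh, ds.persons)
        rng = np.random.default_rng(2)
        poor = (rng.random(len(hh)) < 0.4).astype(float)
        out = group_prevalences(hh, poor, outcomes).set_index("outcome")
        w = hh["weight"].to_numpy()
        for name in outcomes.columns:
            x = outcomes[name].to_numpy()
            expected = loop_weighted_prevalence(x, w, poor == 1.0)
            assert out.loc[name, "prev_poor"] == pytest.approx(expected, abs=1e-12)
            expected_r = loop_weighted_prevalence(x, w, poor == 0.0)
            assert out.loc[name, "prev_rich"] == pytest.approx(expected_r, abs=1e-12)

    def test_empty_group_is_missing_not_zero(self):
        hh = pd.DataFrame({"household_id": ["a", "b"], "city_id": "c1", "weight": [1.0, 1.0]})
        out = group_prevalences(hh, [1.0, 1.0], pd.DataFrame({"x": [1.0, 0.0]}))
        assert np.isnan(out["prev_rich"].iloc[0])
        assert out["n_rich"].iloc[0] == 0


class TestQuadrantRule:
    # hand-written truth table over the band-edge grid
    TRUTH = {
        # (prev, gap) -> class; prev bands: <5 low, [5,15] intermediate, >15 high
        (3.0, -2.0): "good",
        (3.0, -20.0): "intermediate",
        (0.0, 0.0): "good",
        (4.9, 5.0): "good",        # |gap| = 5 is low inequality (inclusive)
        (4.9, -5.1): "intermediate",
        (5.0, 0.0): "intermediate",   # prev 5 belongs to the intermediate band
        (15.0, 4.9): "intermediate",  # prev 15 belongs to the intermediate band
        (15.0, -50.0): "worse",
        (15.1, 0.0): "worse",         # high prevalence, low inequality -> worse (extension)
        (90.0, 0.0): "worse",
        (90.0, -50.0): "worse",
        (10.0, 5.1): "worse",
        (10.0, -4.9): "intermediate",
    }

    @pytest.mark.parametrize("prev,gap", sorted(TRUTH))
    def test_matches_truth_table(self, prev, gap):
        assert classify_performance(prev, gap) == self.TRUTH[(prev, gap)]

    def test_exhaustive_grid_piecewise_constant(self):
        rule = PerformanceRule()
        for prev in (0, 4.9, 5, 10, 15, 15.1, 90):
            for gap in (0, 4.9, -4.9, 5, -5, 5.1, -5.1, 50, -50):
                cls = classify_performance(prev, gap, rule)
                p = "low" if prev < 5 else ("intermediate" if prev <= 15 else "high")
                g = "low" if abs(gap) <= 5 else "high"
                expected = {("low", "low"): "good",
                            ("intermediate", "low"): "intermediate",
                            ("low", "high"): "intermediate",
                            ("intermediate", "high"): "worse",
                            ("high", "high"): "worse",
                            ("high", "low"): "worse"}[(p, g)]
                assert cls == expected

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            classify_performance(120.0, 0.0)
        with pytest.raises(ValueError):
            classify_performance(10.0, 150.0)


class TestPerformanceTable:
    def _summaries(self):
        rows = []
        for city, prev, gap in [("a", 0.02, -0.01), ("b", 0.5, -0.4)]:
            for out in ("no_electricity", "low_education"):
                rows.append({"city_id": city, "outcome": out, "prev_poor": prev,
                             "prev_rich": prev + gap if gap < 0 else prev,
                             "prev_overall": prev, "gap": gap})
        return pd.DataFrame(rows)

    def test_counts_per_city(self):
        table = performance_table(self._summaries())
        assert table.loc["a", "n_good"] == 2
        assert table.loc["b", "n_worse"] == 2

    def test_city_with_high_prev_and_gap_worse_on_all(self):
        rows = [{"city_id": "x", "outcome": o, "prev_poor": 0.9, "prev_rich": 0.3,
                 "prev_overall": 0.7, "gap": -0.6}
                for o in ("out_of_school", "low_education", "no_electricity",
                          "no_improved_water", "no_improved_sanitation")]
        table = performance_table(pd.DataFrame(rows))
        assert table.loc["x", "n_worse"] == 5

    def test_order_invariance(self):
        s = self._summaries()
        t1 = performance_table(s)
        t2 = performance_table(s.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(t1, t2)


class TestContextCorrelations:
    def _frame(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        hdi = rng.uniform(0.3, 0.8, n)
        rows = []
        for i in range(n):
            rows.append({"city_id": f"c{i}", "outcome": "no_electricity",
                         "prev_poor": 1 - hdi[i] + 0.05 * rng.standard_normal(),
                         "prev_rich": 0.2, "gap": -0.3})
        ctx = pd.DataFrame({"city_id": [f"c{i}" for i in range(n)], "hdi": hdi,
                            "health_index": hdi, "education_index": hdi,
                            "income_index": hdi})
        return pd.DataFrame(rows), ctx

    def test_identity_gives_r_one(self):
        summaries, ctx = self._frame()
        summaries["prev_poor"] = ctx["hdi"].to_numpy()
        out = context_correlations(summaries, ctx)
        cell = out[(out["statistic"] == "prev_poor") & (out["index"] == "hdi")].iloc[0]
        assert cell["r"] == pytest.approx(1.0)

    def test_degenerate_variance_flagged(self):
        summaries, ctx = self._frame()
        out = context_correlations(summaries, ctx)
        cell = out[(out["statistic"] == "prev_rich") & (out["index"] == "hdi")].iloc[0]
        assert np.isnan(cell["r"]) and cell["flag"] == "undefined"

    def test_negative_relationship_detected_with_ci(self):
        summaries, ctx = self._frame()
        out = context_correlations(summaries, ctx)
        cell = out[(out["statistic"] == "prev_poor") & (out["index"] == "hdi")].iloc[0]
        assert cell["r"] < -0.8
        assert cell["ci_low"] <= cell["r"] <= cell["ci_high"]

    def test_fisher_ci_width_shrinks_with_n(self):
        import math
        from urbanpoverty.performance import _fisher_ci
        widths = [np.diff(_fisher_ci(0.5, n))[0] for n in (10, 50, 200)]
        assert widths[0] > widths[1] > widths[2]


class TestExports:
    def test_equiplot_cardinality_and_determinism(self, tmp_path, small_scenario):
        from urbanpoverty import RunSettings, run_pipeline
        res = run_pipeline(small_scenario, RunSettings())
        files = export_tidy_outputs(res.city_summaries, res.correlations,
                                    res.performance, tmp_path / "a")
        eq = pd.read_csv(files["equiplot"])
        n_cities = res.city_summaries["city_id"].nunique()
        assert len(eq) == n_cities * 2 * 5
        export_tidy_outputs(res.city_summaries, res.correlations,
                            res.performance, tmp_path / "b")
        for name in ("equiplot.csv", "quadrant.csv", "correlations.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_quadrant_classes_match_classifier(self, tmp_path, small_scenario):
        from urbanpoverty import RunSettings, run_pipeline
        res = run_pipeline(small_scenario, RunSettings())
        files = export_tidy_outputs(res.city_summaries, res.correlations,
                                    res.performance, tmp_path)
        quad = pd.read_csv(files["quadrant"])
        for _, row in quad.iterrows():
            if row["performance"] == "missing":
                continue
            assert row["performance"] == classify_performance(row["prevalence_pct"], row["gap_pp"])
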