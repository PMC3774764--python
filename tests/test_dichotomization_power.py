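"""Tests for the dichotomization power study: classification, PSU collapse,
bivariate PSU regressions and the Monte Carlo driver."""

import numpy as np
import pandas as pd
import pytest

from ecostunt import ChildGenParams, children_to_frame, gen_children
from ecostunt.dichotomization_power import (
    bivariate_psu_regression,
    classify_child,
    collapse_to_psu,
    run_power_study,
    summaries_to_frame,
    summarize_distributions,
)
from ecostunt.regression_core import DataError, ParameterError
from ecostunt.synthetic_data import ChildRecord


class TestClassifyChild:
    @pytest.mark.parametrize(
        "haz,stunted,severe",
        [
            (-2.5, True, False),
            (-2.0, False, False),  # strict inequality at the cutoff
            (-3.0, True, False),
            (-4.0, True, True),
            (0.3, False, False),
        ],
    )
    def test_threshold_convention(self, haz, stunted, severe):
        assert classify_child(haz) == (stunted, severe)

    def test_severe_implies_stunted_everywhere(self):
        for haz in np.linspace(-6, 3, 901):
            stunted, severe = classify_child(haz)
            assert not severe or stunted

    def test_non_finite_rejected(self):
        with pytest.raises(DataError):
            classify_child(float("nan"))


class TestCollapseToPsu:
    def test_two_child_hand_computation(self):
        kids = [ChildRecord("A", 1, -3.0), ChildRecord("A", 0, -1.0)]
        (s,) = collapse_to_psu(kids)
        assert s.mean_haz == pytest.approx(-2.0)
        assert s.frac_stunted == pytest.approx(0.5)  # -3 is stunted, -1 is not
        assert s.frac_severe == 0.0  # -3 is not strictly below -3
        assert s.od_fraction == pytest.approx(0.5)
        assert s.n_children == 2

    def test_three_psu_fixture_hand_values(self):
        """Spreadsheet-style oracle prepared by hand."""
        kids = [
            ChildRecord("A", 1, -3.5), ChildRecord("A", 1, -2.5), ChildRecord("A", 0, -0.5),
            ChildRecord("B", 0, -2.1), ChildRecord("B", 0, 1.0),
            ChildRecord("C", 1, -3.2),
        ]
        out = {s.psu_id: s for s in collapse_to_psu(kids)}
        assert out["A"].mean_haz == pytest.approx(-6.5 / 3)
        assert out["A"].frac_stunted == pytest.approx(2 / 3)
        assert out["A"].frac_severe == pytest.approx(1 / 3)
        assert out["A"].od_fraction == pytest.approx(2 / 3)
        assert out["B"].frac_stunted == pytest.approx(0.5)
        assert out["B"].od_fraction == 0.0
        assert out["C"].frac_severe == 1.0 and out["C"].n_children == 1

    def test_severe_nested_in_stunted(self, child_frame):
        for s in collapse_to_psu(child_frame):
            assert s.frac_severe <= s.frac_stunted
            assert 0 <= s.od_fraction <= 1

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            collapse_to_psu([])


class TestBivariatePsuRegression:
    def test_perfectly_linear_outcome(self):
        df = pd.DataFrame(
            {
                "psu_id": list("ABCD"),
                "od_fraction": [0.1, 0.3, 0.6, 0.9],
                "mean_haz": [-1.2, -1.6, -2.2, -2.8],
                "frac_stunted": [0.2, 0.3, 0.5, 0.6],
                "frac_severe": [0.1, 0.1, 0.2, 0.3],
                "n_children": [10, 10, 10, 10],
            }
        )
        slope, t, r2 = bivariate_psu_regression(df, "mean_haz")
        assert slope == pytest.approx(-2.0, rel=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_normal_equations_oracle_on_five_psus(self):
        od = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        y = np.array([-1.0, -1.8, -1.5, -2.6, -2.2])
        df = pd.DataFrame(
            {"psu_id": list("ABCDE"), "od_fraction": od, "mean_haz": y,
             "frac_stunted": 0.5, "frac_severe": 0.1, "n_children": 5}
        )
        slope, t, r2 = bivariate_psu_regression(df, "mean_haz")
        sxx = np.sum((od - od.mean()) ** 2)
        sxy = np.sum((od - od.mean()) * (y - y.mean()))
        expected_slope = sxy / sxx
        assert slope == pytest.approx(expected_slope, rel=1e-10)
        resid = y - (y.mean() - expected_slope * od.mean()) - expected_slope * od
        expected_r2 = 1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
        assert r2 == pytest.approx(expected_r2, rel=1e-10)

    def test_order_invariance(self, child_frame):
        summaries = collapse_to_psu(child_frame)
        fwd = bivariate_psu_regression(summaries, "frac_stunted")
        rev = bivariate_psu_regression(list(reversed(summaries)), "frac_stunted")
        assert fwd == pytest.approx(rev)

    def test_too_few_psus(self):
        df = summaries_to_frame(collapse_to_psu([ChildRecord("A", 1, -3.0)]))
        with pytest.raises(DataError):
            bivariate_psu_regression(df, "mean_haz")


@pytest.fixture(scope="module")
def small_children():
    return children_to_frame(
        gen_children(ChildGenParams(n_psu=100, children_per_psu=20, seed=21))
    )


class TestRunPowerStudy:

    def test_seed_reproducibility(self, small_children):
        a = run_power_study(small_children, sample_size=500, n_reps=5, seed=3)
        b = run_power_study(small_children, sample_size=500, n_reps=5, seed=3)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)
        assert a.summary == b.summary

    def test_replicates_consistent_with_single_pipeline_pass(self, small_children):
        """Replicate rows equal an independent re-run of sample -> collapse ->
        regress with the same random draws."""
        res = run_power_study(small_children, sample_size=500, n_reps=3, seed=9)
        rng = np.random.default_rng(9)
        for rep in range(3):
            idx = rng.choice(len(small_children), size=500, replace=False)
            summaries = collapse_to_psu(small_children.iloc[idx])
            for outcome in ("mean_haz", "frac_stunted", "frac_severe"):
                slope, t, r2 = bivariate_psu_regression(summaries, outcome)
                row = res.replicates.query("rep == @rep and outcome == @outcome").iloc[0]
                assert row.slope == pytest.approx(slope, rel=1e-9)
                assert row.t == pytest.approx(t, rel=1e-9)
                assert row.r2 == pytest.approx(r2, rel=1e-9)

    def test_sample_size_exceeding_population_rejected(self, small_children):
        with pytest.raises(ParameterError):
            run_power_study(small_children, sample_size=10**6, n_reps=1, seed=0)

    def test_win_fractions_in_unit_interval(self, small_children):
        res = run_power_study(small_children, sample_size=800, n_reps=10, seed=1)
        for v in res.summary.values():
            assert 0.0 <= v <= 1.0

    def test_degenerate_step_function_haz_closes_power_gap(self):
        """When haz is a deterministic step at the stunting cutoff, the
        continuous mean and the stunted fraction carry identical information,
        so their regressions have identical R2."""
        rng = np.random.default_rng(17)
        rows = []
        for p in range(40):
            rate = rng.uniform(0.05, 0.95)
            for _ in range(25):
                below = rng.random() < rate
                rows.append(
                    {"psu_id": f"P{p:02d}", "od_household": int(rng.random() < rate),
                     "haz": -2.5 if below else -1.5}
                )
        df = pd.DataFrame(rows)
        summaries = collapse_to_psu(df)
        _, t_c, r2_c = bivariate_psu_regression(summaries, "mean_haz")
        _, t_d, r2_d = bivariate_psu_regression(summaries, "frac_stunted")
        assert r2_c == pytest.approx(r2_d, abs=1e-10)
        assert abs(t_c) == pytest.approx(abs(t_d), rel=1e-8)

    def test_win_fraction_monotone_in_effect_size(self):
        """Larger effect relative to haz_sd gives the continuous outcome at
        least as large an R2 win fraction (seeded small grid)."""
        wins = []
        for delta in (-0.5, -2.0, -4.0):
            kids = children_to_frame(
                gen_children(
                    ChildGenParams(n_psu=150, children_per_psu=15, delta_haz=delta,
                                   haz_sd=1.2, seed=29)
                )
            )
            res = run_power_study(kids, sample_size=1500, n_reps=30, seed=31)
            wins.append(res.summary["win_fraction_r2"])
        assert wins[0] <= wins[1] + 0.1 and wins[1] <= wins[2] + 0.1


class TestSummarizeDistributions:
    def test_bin_counts_conserve_replicates(self, child_frame):
        res = run_power_study(child_frame, sample_size=600, n_reps=8, seed=2)
        tables = summarize_distributions(res)
        for stat in ("r2", "t"):
            per_outcome = tables[stat].groupby("outcome")["count"].sum()
            assert (per_outcome == res.n_reps).all()

    def test_win_fractions_match_recount(self, child_frame):
        res = run_power_study(child_frame, sample_size=600, n_reps=12, seed=4)
        wide = res.replicates.pivot(index="rep", columns="outcome", values="r2")
        recount = np.mean(
            (wide.mean_haz > wide.frac_stunted) & (wide.mean_haz > wide.frac_severe)
        )
        assert res.summary["win_fraction_r2"] == pytest.approx(float(recount))

    def test_single_replicate_point_mass(self, child_frame):
        res = run_power_study(child_frame, sample_size=600, n_reps=1, seed=5)
        tables = summarize_distributions(res)
        for stat in ("r2", "t"):
            assert (tables[stat].groupby("outcome")["count"].sum() == 1).all()
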