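import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pstfst import (
    SimulationConfig,
    TraitObservations,
    TraitSpec,
    anova_components,
    classify_selection,
    critical_c_ratio,
    pst_bootstrap,
    pst_curve,
    pst_point,
    simulate_traits,
)
from pstfst.pst_analysis import AnovaComponents


def observations(groups: dict[str, list[float]], trait: str = "t") -> TraitObservations:
    ids, labels, values = [], [], []
    for pop, vals in groups.items():
        for v in vals:
            ids.append(f"i{len(ids)}")
            labels.append(pop)
            values.append([v])
    return TraitObservations(ids, labels, [trait], np.array(values))


class TestAnovaComponents:
    def test_hand_arithmetic(self):
        comp = anova_components(observations({"a": [1, 2, 3], "b": [3, 4, 5]}), "t")
        assert comp.msb == pytest.approx(6.0)
        assert comp.msw == pytest.approx(1.0)
        assert (comp.df_between, comp.df_within) == (1, 4)

    def test_identical_means_zero_between(self):
        comp = anova_components(observations({"a": [1, 3], "b": [0, 4]}), "t")
        assert comp.msb == pytest.approx(0.0)

    def test_paper_fpl_drops_unmeasured_population(self, paper_tables):
        summary, _, _ = paper_tables
        comp = anova_components(summary, "FPL")
        assert comp.k == 10
        assert comp.n_total == 68
        assert "PA" not in comp.populations

    def test_summary_and_individual_agree(self, rng):
        groups = {f"p{i}": list(rng.normal(i, 1.0, size=rng.integers(3, 9)))
                  for i in range(5)}
        obs = observations(groups)
        from_obs = anova_components(obs, "t")
        from_summary = anova_components(obs.to_summary(), "t")
        assert from_obs.msb == pytest.approx(from_summary.msb, abs=1e-12)
        assert from_obs.msw == pytest.approx(from_summary.msw, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            anova_components(observations({"a": [1, 2]}), "t")
        with pytest.raises(ValueError):
            anova_components(observations({"a": [1], "b": [2]}), "t")


class TestPstPoint:
    def test_printed_table_values(self, paper_tables):
        summary, _, _ = paper_tables
        assert pst_point(anova_components(summary, "SSL"), 0.5) == \
            pytest.approx(0.580, abs=0.005)
        assert pst_point(anova_components(summary, "FRW"), 0.5) == \
            pytest.approx(0.867, abs=0.01)
        assert pst_point(anova_components(summary, "FRL"), 0.5) == \
            pytest.approx(0.867, abs=0.01)

    def test_simple_ratios(self):
        assert pst_point(AnovaComponents("t", 0.0, 1.0, 3, 30), 0.7) == 0.0
        assert pst_point(AnovaComponents("t", 6.0, 1.0, 3, 30), 1.0) == \
            pytest.approx(0.75)

    @given(st.floats(min_value=0.01, max_value=5.0),
           st.floats(min_value=0.01, max_value=5.0))
    @settings(max_examples=30, deadline=None)
    def test_strictly_increasing_in_c_with_limits(self, msb, msw):
        comp = AnovaComponents("t", msb, msw, 4, 40)
        values = [pst_point(comp, c) for c in (0.01, 0.5, 1.0, 2.0, 10.0)]
        assert all(a < b for a, b in zip(values, values[1:]))
        assert pst_point(comp, 1e-9) < 1e-6
        assert pst_point(comp, 1e9) > 1 - 1e-6

    def test_affine_invariance(self, rng):
        groups = {f"p{i}": list(rng.normal(i, 1.0, 8)) for i in range(4)}
        base = pst_point(anova_components(observations(groups), "t"), 0.5)
        scaled = {p: [3.7 * v - 11.0 for v in vals] for p, vals in groups.items()}
        again = pst_point(anova_components(observations(scaled), "t"), 0.5)
        assert again == pytest.approx(base, abs=1e-12)


class TestBootstrap:
    def test_ci_brackets_point(self, paper_tables):
        summary, _, _ = paper_tables
        est = pst_bootstrap(summary, "FRW", 0.5, n_boot=999, seed=8)
        assert est.ci_low <= est.pst <= est.ci_high

    def test_degenerate_within_variance_collapses(self):
        obs = observations({"a": [1.0] * 6, "b": [2.0] * 6})
        est = pst_bootstrap(obs, "t", 0.5, n_boot=500, seed=1)
        assert est.ci_high - est.ci_low < 1e-6

    def test_more_individuals_narrow_the_interval(self, rng):
        widths = {8: [], 16: []}
        for seed in range(20):
            for n in widths:
                config = SimulationConfig(
                    n_pops=6, n_individuals=n,
                    traits=[TraitSpec("t", 1.0, 0.6)],
                )
                tr = simulate_traits(config, seed=seed)
                est = pst_bootstrap(tr, "t", 1.0, n_boot=299, seed=seed + 50)
                widths[n].append(est.ci_high - est.ci_low)
        assert np.mean(widths[16]) < np.mean(widths[8])

    def test_small_bootstrap_rejected(self, paper_tables):
        summary, _, _ = paper_tables
        with pytest.raises(ValueError):
            pst_bootstrap(summary, "FRW", n_boot=50)

    def test_point_recovery_on_simulated_traits(self):
        for target in (0.5, 0.8):
            points = []
            for seed in range(30):
                config = SimulationConfig(
                    n_individuals=15, traits=[TraitSpec("t", 1.0, target)]
                )
                tr = simulate_traits(config, seed=seed)
                est = pst_bootstrap(tr, "t", 1.0, n_boot=299, seed=seed + 1000)
                points.append(est.pst)
            assert abs(np.mean(points) - target) < 0.1


class TestCriticalRatio:
    def test_bisection_matches_dense_grid(self, rng):
        grid = np.arange(0.001, 2.0005, 0.001)
        for seed in range(10):
            config = SimulationConfig(
                n_pops=8, n_individuals=10, traits=[TraitSpec("t", 1.0, 0.6)]
            )
            tr = simulate_traits(config, seed=seed)
            est = pst_bootstrap(tr, "t", n_boot=499, seed=seed + 7)
            by_bisect = critical_c_ratio(None, "t", 0.33, estimate=est, tol=1e-4)
            by_grid = critical_c_ratio(None, "t", 0.33, estimate=est, grid=grid)
            if math.isinf(by_grid):
                assert math.isinf(by_bisect)
            else:
                assert abs(by_bisect - by_grid) < 0.002

    def test_zero_fst_hits_smallest_grid_value(self, paper_tables):
        summary, _, _ = paper_tables
        est = pst_bootstrap(summary, "FRW", n_boot=499, seed=3)
        grid = np.arange(0.05, 2.01, 0.05)
        assert critical_c_ratio(None, "FRW", 0.0, estimate=est, grid=grid) == \
            pytest.approx(0.05)

    def test_invalid_fst(self, paper_tables):
        summary, _, _ = paper_tables
        with pytest.raises(ValueError):
            critical_c_ratio(summary, "FRW", 1.5)


class TestClassification:
    def test_strong_diversifying_for_fruit_width(self, paper_tables):
        summary, _, _ = paper_tables
        est = pst_bootstrap(summary, "FRW", 0.5, n_boot=1999, seed=11)
        est.critical_ratio = critical_c_ratio(None, "FRW", 0.329, estimate=est)
        assert est.critical_ratio <= 0.5
        assert classify_selection(est, 0.329) == "diversifying_strong"

    def test_weak_support_for_peduncle_length(self, paper_tables):
        summary, _, _ = paper_tables
        est = pst_bootstrap(summary, "FPL", 0.5, n_boot=1999, seed=11)
        est.critical_ratio = critical_c_ratio(None, "FPL", 0.329, estimate=est)
        assert classify_selection(est, 0.329) in (
            "diversifying_weak", "diversifying_strong"
        )

    def test_indistinguishable_when_ci_straddles(self):
        rng = np.random.default_rng(0)
        # no between-population signal: P_ST CI straddles a matched F_ST
        groups = {f"p{i}": list(rng.normal(0.0, 1.0, 10)) for i in range(6)}
        est = pst_bootstrap(observations(groups), "t", n_boot=999, seed=5)
        est.critical_ratio = critical_c_ratio(None, "t", 0.6, estimate=est)
        assert classify_selection(est, 0.6) == "indistinguishable"

    def test_stabilising_when_ci_below_fst(self):
        rng = np.random.default_rng(1)
        groups = {f"p{i}": list(rng.normal(0.0, 1.0, 10)) for i in range(6)}
        est = pst_bootstrap(observations(groups), "t", n_boot=999, seed=5)
        est.critical_ratio = critical_c_ratio(None, "t", 0.99, estimate=est)
        assert classify_selection(est, 0.99) == "uniform_stabilising"


class TestCurve:
    def test_monotone_in_c(self, paper_tables):
        summary, _, _ = paper_tables
        est = pst_bootstrap(summary, "SSL", n_boot=499, seed=2)
        curve = pst_curve(est)
        assert len(curve) == 40  # default grid 0.05 .. 2.0 step 0.05
        assert curve["pst"].is_monotonic_increasing
        assert curve["ci_low"].is_monotonic_increasing
        assert (curve["ci_low"] <= curve["ci_high"]).all()
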