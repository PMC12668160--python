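import numpy as np
import pytest

from crcscreen.natural_history import nh_forward_summary
from crcscreen.sensitivity import (
    DsaRange,
    ParamDistribution,
    ScenarioSpec,
    adherence_grid,
    default_psa_distributions,
    fit_distribution,
    one_way_dsa,
    run_psa,
    run_scenarios,
    solve_onset_scale,
)


@pytest.fixture(scope="module")
def tiny_inputs(bundle):
    """1,000-person inputs so DSA/PSA smoke runs stay fast."""
    from crcscreen.natural_history import CohortConfig
    from crcscreen.pipeline import ModelInputs

    return ModelInputs(
        params=bundle.truth_params,
        lifetable=bundle.lifetable,
        survival=bundle.survival,
        costs=bundle.costs,
        tests=bundle.tests,
        weights=bundle.weights,
        strategies={"FIT": bundle.strategies["FIT"], "Colo": bundle.strategies["Colo"]},
        cohort=CohortConfig(n=1000, seed=77),
    )


class TestFitDistribution:
    def test_gamma_method_of_moments(self):
        d = ParamDistribution("costs.values.test_fit", "gamma", 100.0, 20.0)
        # shape 25, scale 4
        rng = np.random.default_rng(0)
        draws = np.array([fit_distribution(d)(rng) for _ in range(20_000)])
        assert draws.mean() == pytest.approx(100.0, rel=0.01)
        assert draws.std() == pytest.approx(20.0, rel=0.05)

    def test_beta_moment_matching(self):
        d = ParamDistribution("tests.fit.specificity", "beta", 0.5, 0.1)
        # nu = 0.25/0.01 - 1 = 24 -> alpha = beta = 12
        rng = np.random.default_rng(1)
        draws = np.array([fit_distribution(d)(rng) for _ in range(20_000)])
        assert draws.mean() == pytest.approx(0.5, abs=0.005)
        assert draws.std() == pytest.approx(0.1, rel=0.05)

    def test_zero_se_degenerate(self):
        d = ParamDistribution("weights.treatment", "beta", 0.3, 0.0)
        sampler = fit_distribution(d)
        assert sampler(np.random.default_rng(0)) == 0.3

    def test_infeasible_beta_reports_bound(self):
        d = ParamDistribution("weights.treatment", "beta", 0.5, 0.6)
        with pytest.raises(ValueError, match="se must be <"):
            fit_distribution(d)

    def test_invalid_families_rejected(self):
        with pytest.raises(ValueError):
            ParamDistribution("x", "normal", 1.0, 0.1)
        with pytest.raises(ValueError):
            ParamDistribution("x", "beta", 1.5, 0.1)


class TestOneWayDsa:
    def test_degenerate_range_zero_width(self, tiny_inputs):
        base = tiny_inputs.get_param("costs.values.test_fit")
        df = one_way_dsa(tiny_inputs, [DsaRange("costs.values.test_fit", base, base)], ("NH", "FIT"))
        assert df["bar_width"].iloc[0] == pytest.approx(0.0)
        assert df["icer_low"].iloc[0] == pytest.approx(df["icer_high"].iloc[0])

    def test_fit_cost_raises_fit_icer(self, tiny_inputs):
        base = tiny_inputs.get_param("costs.values.test_fit")
        df = one_way_dsa(
            tiny_inputs, [DsaRange("costs.values.test_fit", base * 0.5, base * 2)], ("NH", "FIT")
        )
        assert df["icer_high"].iloc[0] > df["icer_low"].iloc[0]

    def test_output_invariant_to_range_order(self, tiny_inputs):
        ranges = [
            DsaRange("costs.values.test_fit", 1.0, 50.0),
            DsaRange("costs.values.colonoscopy_followup", 50.0, 600.0),
        ]
        a = one_way_dsa(tiny_inputs, ranges, ("NH", "FIT"))
        b = one_way_dsa(tiny_inputs, list(reversed(ranges)), ("NH", "FIT"))
        assert a.equals(b)

    def test_invalid_range_rejected_before_any_run(self, tiny_inputs):
        with pytest.raises(ValueError, match="violated"):
            one_way_dsa(tiny_inputs, [DsaRange("costs.values.test_fit", 900.0, 1000.0)], ("NH", "FIT"))


class TestRunPsa:
    def test_degenerate_se_reproduces_base_and_step_ceac(self, tiny_inputs):
        from crcscreen.pipeline import evaluate_strategies

        dists = default_psa_distributions(tiny_inputs, se_frac=0.0)
        res = run_psa(tiny_inputs, dists, n_iter=3, wtp_grid=[0.0, 5_000.0, 50_000.0], seed=5)
        base = evaluate_strategies(tiny_inputs)
        for name, o in base.items():
            got = res.iterations[res.iterations["strategy"] == name]
            assert (got["cost"] == o.mean_cost).all()
            assert (got["effect"] == o.dalys_averted).all()
        strategies = ["NH", "FIT", "Colo"]
        np.testing.assert_allclose(res.ceac[strategies].sum(axis=1), 1.0)
        # a step function: each WTP row is a point mass
        assert ((res.ceac[strategies] == 1.0).sum(axis=1) == 1).all()

    def test_ceac_normalized_and_wtp_zero_prefers_cheapest(self, tiny_inputs):
        dists = default_psa_distributions(tiny_inputs, se_frac=0.2)
        res = run_psa(tiny_inputs, dists, n_iter=8, wtp_grid=[0.0, 10_000.0], seed=9)
        strategies = ["NH", "FIT", "Colo"]
        np.testing.assert_allclose(res.ceac[strategies].sum(axis=1), 1.0)
        # NMB at WTP 0 is -cost: the least costly strategy wins every iteration
        cheapest = (
            res.iterations.pivot(index="iteration", columns="strategy", values="cost")
            .idxmin(axis=1)
            .value_counts(normalize=True)
        )
        at_zero = res.ceac.iloc[0]
        for s in strategies:
            assert at_zero[s] == pytest.approx(float(cheapest.get(s, 0.0)))

    def test_reproducible_under_seed(self, tiny_inputs):
        dists = default_psa_distributions(tiny_inputs, se_frac=0.2)
        a = run_psa(tiny_inputs, dists, n_iter=3, wtp_grid=[10_000.0], seed=4)
        b = run_psa(tiny_inputs, dists, n_iter=3, wtp_grid=[10_000.0], seed=4)
        assert a.iterations.equals(b.iterations)


class TestScenarios:
    def test_empty_list_base_case_only(self, tiny_inputs):
        res = run_scenarios(tiny_inputs, [])
        assert list(res) == ["base"]

    def test_onset_scale_bisection_hits_target(self, tiny_inputs):
        base = nh_forward_summary(tiny_inputs.params, tiny_inputs.lifetable).lifetime_incidence
        for scale in (0.5, 2.0):
            mult = solve_onset_scale(tiny_inputs, scale)
            p = tiny_inputs.params.copy()
            p.values["p_adenoma_onset"] = p.values["p_adenoma_onset"] * mult
            got = nh_forward_summary(p, tiny_inputs.lifetable).lifetime_incidence
            assert got == pytest.approx(scale * base, rel=0.011)

    def test_start_age_scenarios_share_nh_row(self, tiny_inputs):
        res = run_scenarios(
            tiny_inputs,
            [ScenarioSpec(name="start40", start_age=40), ScenarioSpec(name="start50", start_age=50)],
        )
        nh_rows = {
            name: tab[tab["strategy"] == "NH"][["cost", "crc_cases_per_100k"]].iloc[0]
            for name, tab in res.items()
        }
        for name in ("start40", "start50"):
            assert nh_rows[name].equals(nh_rows["base"])

    def test_switch_scenario_adds_composite_strategy(self, tiny_inputs):
        res = run_scenarios(tiny_inputs, [ScenarioSpec(name="switch", fit_colo_switch=True)])
        assert "FIT-Colo" in set(res["switch"]["strategy"])

    def test_adherence_grid_contains_requested_points(self, tiny_inputs):
        g = adherence_grid(tiny_inputs, "FIT", [0.5, 1.0], [1.0])
        assert len(g) == 2
        assert set(g["adherence"]) == {0.5, 1.0}
        assert (g["incidence_reduction"] <= 1.0).all()
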