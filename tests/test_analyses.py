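import numpy as np
import pytest

from deprev import analyses as an
from deprev.cohort_model import Arm, cases_prevented
from deprev.psa import run_psa


class TestScenarioEngine:
    def test_empty_overrides_reproduce_base_case(self, fixture_set):
        sc = an.Scenario(label="noop")
        res = an.run_scenario(fixture_set, sc, n_sims=50, seed=4)
        base = run_psa(fixture_set, n_sims=50, seed=4)
        for arm in Arm:
            assert np.array_equal(res.psa.cost[arm], base.cost[arm])
            assert np.array_equal(res.psa.qalys[arm], base.qalys[arm])

    def test_apply_then_revert_override_is_identity(self, fixture_set):
        changed = an.apply_scenario(
            fixture_set, an.Scenario(label="x", overrides={"or_targeted": 0.5})
        )
        reverted = an.apply_scenario(
            changed, an.Scenario(label="y", overrides={"or_targeted": 0.66})
        )
        assert reverted.point == fixture_set.point
        orig = fixture_set.dists["or_targeted"]
        back = reverted.dists["or_targeted"]
        assert back.ci_low == pytest.approx(orig.ci_low)
        assert back.ci_high == pytest.approx(orig.ci_high)

    def test_threshold_scenarios_order_prevented_cases(self, fixture_set):
        base = cases_prevented(fixture_set.point, Arm.PREDICTD)
        mid = cases_prevented(
            an.apply_scenario(fixture_set, an.SCENARIO_PRESETS["threshold_0154"]).point,
            Arm.PREDICTD,
        )
        high = cases_prevented(
            an.apply_scenario(fixture_set, an.SCENARIO_PRESETS["threshold_0183"]).point,
            Arm.PREDICTD,
        )
        assert base > mid > high
        assert round(mid) == 14
        assert round(high) == 11

    def test_alternative_or_scenarios(self, fixture_set):
        # GP-recruited studies (OR 0.6) and interpersonal therapy (OR 0.13)
        gp = cases_prevented(
            an.apply_scenario(fixture_set, an.SCENARIO_PRESETS["gp_only"]).point,
            Arm.PREDICTD,
        )
        ip = cases_prevented(
            an.apply_scenario(fixture_set, an.SCENARIO_PRESETS["ip"]).point,
            Arm.PREDICTD,
        )
        non_ip = cases_prevented(
            an.apply_scenario(fixture_set, an.SCENARIO_PRESETS["non_ip"]).point,
            Arm.PREDICTD,
        )
        base = cases_prevented(fixture_set.point, Arm.PREDICTD)
        assert round(gp) == 18
        assert round(ip) == 39
        assert round(non_ip) == 11
        assert ip > gp > base > non_ip


class TestMaxAffordableCost:
    def test_no_effect_affords_no_positive_cost(self, fixture_set):
        res = an.max_affordable_cost(fixture_set, 1.0, reps=50, seed=0)
        assert res.status == "ok"
        assert res.max_cost <= 0.0
        assert abs(res.f_at_root) < 0.01

    def test_root_satisfies_tolerance_at_base_or(self, fixture_set):
        res = an.max_affordable_cost(fixture_set, 0.66, reps=100, seed=1)
        assert res.status == "ok"
        assert abs(res.f_at_root) < 0.01
        # anchor: low hundreds of GBP
        assert 100.0 < res.max_cost < 250.0

    def test_curve_monotone_under_common_random_numbers(self, fixture_set):
        curve = an.max_cost_curve(
            fixture_set, or_grid=np.array([0.2, 0.4, 0.6, 0.8, 1.0]),
            reps=40, seed=2,
        )
        assert (curve["status"] == "ok").all()
        assert np.all(np.diff(curve["max_cost"]) <= 1e-9)

    def test_strong_prevention_affords_more_than_weak(self, fixture_set):
        strong = an.max_affordable_cost(fixture_set, 0.2, reps=40, seed=3)
        weak = an.max_affordable_cost(fixture_set, 0.9, reps=40, seed=3)
        assert strong.max_cost > weak.max_cost


class TestUptakeSweep:
    def test_zero_uptake_universal_equals_tau(self, fixture_set):
        sweep = an.uptake_sweep(
            fixture_set, percent_grid=np.array([0]), reps=30, seed=5
        )
        row = sweep.iloc[0]
        # at zero uptake the universal arm is TAU: the two split the draws
        # where TAU-like strategies win
        assert row["prob_universal_optimal"] == pytest.approx(row["prob_tau_optimal"])

    def test_universal_qalys_monotone_in_uptake(self, fixture_set):
        from deprev.economics import model_run

        qalys = [
            model_run(fixture_set.point.with_updates(universal_uptake=u))[
                Arm.UNIVERSAL
            ].total_qalys
            for u in np.linspace(0.0, 1.0, 6)
        ]
        assert np.all(np.diff(qalys) >= -1e-12)

    def test_crossover_none_when_universal_never_leads(self, fixture_set):
        grid = an.uptake_sweep(
            fixture_set, percent_grid=np.array([0, 25, 50, 75, 100]),
            reps=40, seed=6,
        )
        lead = grid["prob_universal_optimal"] > grid["prob_predictd_optimal"]
        cross = an.crossover_uptake(fixture_set, reps=40, seed=6)
        if not lead.any():
            assert cross is None

    def test_cost_only_scaling_creates_low_uptake_crossover(self, fixture_set):
        # when programme cost scales with uptake but the effect covers the
        # whole cohort, universal prevention leads at low uptake
        sweep = an.uptake_sweep(
            fixture_set, percent_grid=np.array([0, 5, 100]), reps=40, seed=7,
            effect_scales_with_uptake=False,
        )
        assert (
            sweep.iloc[0]["prob_universal_optimal"]
            > sweep.iloc[0]["prob_predictd_optimal"]
        )
        assert (
            sweep.iloc[-1]["prob_universal_optimal"]
            < sweep.iloc[-1]["prob_predictd_optimal"]
        )
        cross = an.crossover_uptake(
            fixture_set, reps=40, seed=7, effect_scales_with_uptake=False, tol=2.0
        )
        assert cross is not None and 0.0 < cross < 100.0

    def test_crossover_agrees_with_grid_scan(self, fixture_set):
        step = 5.0
        sweep = an.uptake_sweep(
            fixture_set, percent_grid=np.arange(0, 101, step), reps=40, seed=7,
            effect_scales_with_uptake=False,
        )
        lead = (
            sweep["prob_universal_optimal"] > sweep["prob_predictd_optimal"]
        ).to_numpy()
        # last grid point where universal leads
        grid_cross = sweep["uptake_percent"].to_numpy()[np.where(lead)[0][-1]]
        cross = an.crossover_uptake(
            fixture_set, reps=40, seed=7, effect_scales_with_uptake=False, tol=1.0
        )
        assert abs(cross - grid_cross) <= step


@pytest.fixture(scope="module")
def comparison(fixture_set):
    return an.half_cycle_comparison(fixture_set, n_sims=200, seed=8)


class TestHalfCycleComparison:
    def test_correction_reduces_cost_and_raises_qalys_every_draw(self, comparison):
        for arm in Arm:
            assert np.all(
                comparison.treatment_cost_corrected[arm]
                <= comparison.treatment_cost_base[arm]
            )
            assert np.all(
                comparison.qalys_corrected[arm] >= comparison.qalys_base[arm]
            )

    def test_arm_ranking_unchanged_at_headline_wtp(self, fixture_set):
        from deprev.economics import incremental_analysis, model_run

        base = incremental_analysis(model_run(fixture_set.point))
        corrected = incremental_analysis(
            model_run(fixture_set.point.with_updates(half_cycle_correction=True))
        )
        assert base.optimal_arm is corrected.optimal_arm is Arm.PREDICTD

    def test_summary_deltas_signs(self, comparison):
        summary = comparison.summary()
        assert (summary["mean_treatment_cost_delta"] <= 0).all()
        assert (summary["mean_qaly_delta"] >= 0).all()
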