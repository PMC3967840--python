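import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deprev import cohort_model as cm
from deprev.cohort_model import Arm
from deprev.parameters import ScreeningPerformance

from conftest import microsimulate

BASE_SCREEN = ScreeningPerformance(threshold_label=0.133, sensitivity=0.506, specificity=0.8)


class TestStratification:
    def test_base_case_split(self):
        s = cm.stratify_cohort(1000, 0.088, BASE_SCREEN)
        assert s.tp == pytest.approx(44.528)
        assert s.fp == pytest.approx(182.4)
        assert s.fn == pytest.approx(43.472)
        assert s.tn == pytest.approx(729.6)
        assert s.tp + s.fp + s.tn + s.fn == pytest.approx(1000.0)
        assert s.tp + s.fn == pytest.approx(88.0)
        assert s.high_risk_baseline_12m == pytest.approx(44.528 / 226.928, rel=1e-9)
        assert s.low_risk_baseline_12m == pytest.approx(43.472 / 773.072, rel=1e-9)

    def test_perfect_screen(self):
        perfect = ScreeningPerformance(threshold_label=0.1, sensitivity=1.0, specificity=1.0)
        s = cm.stratify_cohort(1000, 0.088, perfect)
        assert s.fp == 0.0 and s.fn == 0.0
        assert s.high_risk_baseline_12m == 1.0
        assert s.low_risk_baseline_12m == 0.0

    def test_useless_screen_sends_all_cases_negative(self):
        useless = ScreeningPerformance(threshold_label=0.1, sensitivity=0.0, specificity=0.8)
        s = cm.stratify_cohort(1000, 0.088, useless)
        assert s.tp == 0.0
        assert s.fn == pytest.approx(88.0)


class TestCycleProbability:
    def test_no_effect_matches_baseline_decomposition(self):
        q0 = cm.build_cycle_probability(0.088, 1.0, 1.0)
        assert q0 == pytest.approx(1.0 - 0.912 ** 0.25, abs=1e-14)
        assert cm.build_cycle_probability(0.088, 0.66, 0.0) == pytest.approx(q0)

    def test_odds_scale_hand_value(self):
        # odds application: 12-month risk 0.059871, quarterly 0.0153154
        q = cm.build_cycle_probability(0.088, 0.66, 1.0, or_application="odds")
        assert q == pytest.approx(0.0153154, abs=2e-6)

    def test_risk_scale_hand_value(self):
        q = cm.build_cycle_probability(0.088, 0.66, 1.0, or_application="risk")
        assert q == pytest.approx(1.0 - (1.0 - 0.088 * 0.66) ** 0.25, abs=1e-12)

    def test_partial_uptake_mixes_twelve_month_risks(self):
        full = cm.build_cycle_probability(0.088, 0.66, 1.0)
        none = cm.build_cycle_probability(0.088, 0.66, 0.0)
        half = cm.build_cycle_probability(0.088, 0.66, 0.5)
        # linear in uptake on the 12-month risk scale
        risk = lambda q: 1.0 - (1.0 - q) ** 4
        assert risk(half) == pytest.approx(0.5 * risk(full) + 0.5 * risk(none), abs=1e-12)

    def test_per_cycle_variant_applies_effect_quarterly(self):
        q = cm.build_cycle_probability(0.088, 0.66, 1.0, per_cycle=True)
        q0 = 1.0 - 0.912 ** 0.25
        assert q == pytest.approx(q0 * 0.66, abs=1e-12)


class TestMarkovEngine:
    def test_zero_incidence_keeps_cohort_well(self):
        t = cm.run_markov(1000, 0.0, 0.3, 4)
        assert t.cumulative_incident_cases == 0.0
        assert np.allclose(t.occupancy[:, 0], 1000.0)

    def test_annual_incidence_reproduced_over_four_cycles(self):
        q = 1.0 - 0.912 ** 0.25
        t = cm.run_markov(1000, q, 0.29289321881345254, 4)
        assert t.cumulative_incident_cases == pytest.approx(88.0, abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(
        q_inc=st.floats(min_value=0.0, max_value=0.9),
        q_rec=st.floats(min_value=0.0, max_value=1.0),
        cycles=st.integers(min_value=1, max_value=12),
    )
    def test_conservation_and_monotonicity(self, q_inc, q_rec, cycles):
        t = cm.run_markov(1000.0, q_inc, q_rec, cycles)
        sums = t.occupancy.sum(axis=1)
        assert np.all(np.abs(sums - 1000.0) < 1e-9)
        assert np.all(t.occupancy >= -1e-12)
        assert np.all(np.diff(t.occupancy[:, 2]) >= -1e-12)  # recovered absorbs
        assert np.all(np.cumsum(t.new_cases) >= -1e-12)

    def test_half_cycle_shifts_half_of_new_entrants(self):
        base = cm.run_markov(1000, 0.05, 0.3, 4, half_cycle=False)
        corr = cm.run_markov(1000, 0.05, 0.3, 4, half_cycle=True)
        shift = 0.5 * base.cumulative_incident_cases
        assert corr.person_cycles_depressed == pytest.approx(
            base.person_cycles_depressed - shift
        )
        assert corr.person_cycles[0] == pytest.approx(base.person_cycles[0] + shift)
        assert corr.person_cycles.sum() == pytest.approx(base.person_cycles.sum())

    def test_agrees_with_individual_microsimulation(self):
        n = 10**5
        q_inc, q_rec, cycles = 0.0228, 0.2929, 4
        traj = cm.run_markov(n, q_inc, q_rec, cycles)
        occ_sim = microsimulate(n, q_inc, q_rec, cycles, np.random.default_rng(42))
        for c in range(1, cycles + 1):
            for s in range(3):
                p = traj.occupancy[c, s] / n
                tol = max(3.0 * np.sqrt(p * (1 - p) / n), 1e-9)
                assert abs(occ_sim[c, s] / n - p) <= tol, (c, s)


class TestArms:
    def test_null_or_makes_targeted_arm_equal_tau(self, fixture_set):
        params = fixture_set.point.with_updates(or_targeted=1.0)
        assert cm.cases_prevented(params, Arm.PREDICTD) == pytest.approx(0.0, abs=1e-9)

    def test_base_case_prevents_fifteen_cases(self, fixture_set):
        prevented = cm.cases_prevented(fixture_set.point, Arm.PREDICTD)
        # n * pi * Se * (1 - OR) = 44.528 * 0.34
        assert prevented == pytest.approx(15.1395, abs=1e-3)
        assert round(prevented) == 15

    def test_universal_arm_prevents_eight_cases(self, fixture_set):
        prevented = cm.cases_prevented(fixture_set.point, Arm.UNIVERSAL)
        assert round(prevented) == 8

    def test_perfect_screen_and_prevention_prevents_all_cases(self, fixture_set):
        params = fixture_set.point.with_updates(
            sensitivity=1.0, specificity=1.0, or_targeted=1e-12
        )
        assert cm.cases_prevented(params, Arm.PREDICTD) == pytest.approx(88.0, abs=1e-6)

    def test_prevented_monotone_in_or_and_sensitivity(self, fixture_set):
        base = fixture_set.point
        prevented_by_or = [
            cm.cases_prevented(base.with_updates(or_targeted=or_), Arm.PREDICTD)
            for or_ in np.linspace(0.05, 1.0, 12)
        ]
        assert np.all(np.diff(prevented_by_or) <= 1e-12)
        prevented_by_se = [
            cm.cases_prevented(base.with_updates(sensitivity=se), Arm.PREDICTD)
            for se in np.linspace(0.1, 1.0, 10)
        ]
        assert np.all(np.diff(prevented_by_se) >= -1e-12)

    def test_conservation_in_every_arm(self, fixture_set):
        for arm in Arm:
            outcome = cm.evaluate_arm(fixture_set.point, arm)
            total = sum(
                t.occupancy.sum(axis=1) for t in outcome.trajectories.values()
            )
            assert np.all(np.abs(total - 1000.0) < 1e-9)

    def test_tidy_export_shape(self, fixture_set):
        frame = cm.trajectories_frame(cm.evaluate_arm(fixture_set.point, Arm.PREDICTD))
        assert set(frame.columns) == {"cycle", "state", "arm", "group", "expected_count"}
        assert len(frame) == 2 * 5 * 3  # two groups, cycles 0..4, three states
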