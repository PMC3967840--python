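"""Decision tree and quarterly three-state Markov cohort engine.

The decision tree splits a screened cohort into the expected true/false
positive/negative counts implied by incidence, sensitivity and specificity.
Each resulting group is rolled through a Markov model with states
``no_major_depression`` -> ``depressed`` -> ``recovered`` (one-directional;
recovered is absorbing over the 12-month horizon, and there is no death
state).  Cohort accounting is in expected (fractional) patients; rounding
happens only at reporting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import epi_math
from .parameters import ModelParameters, ScreeningPerformance

__all__ = [
    "STATES",
    "Arm",
    "RiskStratification",
    "Trajectory",
    "ArmOutcome",
    "stratify_cohort",
    "build_cycle_probability",
    "quarterly_recovery_probability",
    "run_markov",
    "evaluate_arm",
    "cases_prevented",
    "trajectories_frame",
]

STATES = ("no_major_depression", "depressed", "recovered")
_WELL, _DEP, _REC = 0, 1, 2

CYCLE_MONTHS = 3.0


class Arm(str, enum.Enum):
    """The three strategies compared by the model."""

    PREDICTD = "predictd_prevention"
    UNIVERSAL = "universal_prevention"
    TAU = "tau"


@dataclass(frozen=True)
class RiskStratification:
    """Expected screening 2x2 split of a cohort and the group-level risks."""

    tp: float
    fp: float
    tn: float
    fn: float

    @property
    def n_positive(self) -> float:
        return self.tp + self.fp

    @property
    def n_negative(self) -> float:
        return self.tn + self.fn

    @property
    def high_risk_baseline_12m(self) -> float:
        """PPV: 12-month risk among screen-positives under no prevention."""
        return self.tp / self.n_positive if self.n_positive > 0 else 0.0

    @property
    def low_risk_baseline_12m(self) -> float:
        """12-month risk among screen-negatives."""
        return self.fn / self.n_negative if self.n_negative > 0 else 0.0


def stratify_cohort(
    n: float, incidence_12m: float, screening: ScreeningPerformance
) -> RiskStratification:
    """Expected-value decision-tree split of ``n`` patients."""
    if n < 0:
        raise ValueError(f"cohort size must be non-negative, got {n}")
    if not 0.0 <= incidence_12m < 1.0:
        raise ValueError(f"incidence must be in [0, 1), got {incidence_12m}")
    pi, se, sp = incidence_12m, screening.sensitivity, screening.specificity
    return RiskStratification(
        tp=n * pi * se,
        fn=n * pi * (1.0 - se),
        fp=n * (1.0 - pi) * (1.0 - sp),
        tn=n * (1.0 - pi) * sp,
    )


def build_cycle_probability(
    baseline_12m: float,
    odds_ratio: float,
    uptake: float = 1.0,
    or_application: str = "risk",
    per_cycle: bool = False,
) -> float:
    """Per-cycle (3-month) incidence probability for a treated group.

    The effective 12-month risk is the uptake-weighted mixture of the
    treated risk (``apply_effect``) and the untreated baseline, then
    decomposed into a constant quarterly probability through the hazard
    representation.  With ``per_cycle=True`` the effect is instead applied
    to the quarterly baseline probability (alternative convention; the
    default applies it to the 12-month risk).
    """
    if not 0.0 <= uptake <= 1.0:
        raise ValueError(f"uptake must be in [0, 1], got {uptake}")
    if per_cycle:
        q0 = epi_math.rescale_probability(min(baseline_12m, 1.0 - 1e-12), 12.0, CYCLE_MONTHS)
        return (
            uptake * epi_math.apply_effect(q0, odds_ratio, or_application)
            + (1.0 - uptake) * q0
        )
    risk_12m = (
        uptake * epi_math.apply_effect(baseline_12m, odds_ratio, or_application)
        + (1.0 - uptake) * baseline_12m
    )
    # a baseline of exactly 1 (perfect screen) has no finite hazard; clamp
    risk_12m = min(risk_12m, 1.0 - 1e-12)
    return epi_math.rescale_probability(risk_12m, 12.0, CYCLE_MONTHS)


def quarterly_recovery_probability(recovery_prob_6m: float) -> float:
    """Decompose a 6-month recovery probability to the 3-month cycle."""
    if recovery_prob_6m >= 1.0:
        return 1.0
    return epi_math.rescale_probability(recovery_prob_6m, 6.0, CYCLE_MONTHS)


@dataclass(frozen=True)
class Trajectory:
    """State occupancies of one cohort group across cycles 0..C.

    ``occupancy[c, s]`` is the expected count in state ``s`` at the end of
    cycle ``c`` (cycle 0 is the start, everyone well).  ``person_cycles``
    are the state-cycle totals used for costing and QALYs; with the
    half-cycle correction, patients entering the depressed state contribute
    half of their entry cycle to ``depressed`` and the other half to
    ``no_major_depression``.
    """

    group_size: float
    occupancy: np.ndarray  # (cycles+1, 3)
    new_cases: np.ndarray  # (cycles,)
    half_cycle: bool
    person_cycles: np.ndarray = field(init=False)  # (3,)

    def __post_init__(self) -> None:
        pc = self.occupancy[1:].sum(axis=0).astype(float)
        if self.half_cycle:
            shift = 0.5 * float(self.new_cases.sum())
            pc = pc.copy()
            pc[_DEP] -= shift
            pc[_WELL] += shift
        object.__setattr__(self, "person_cycles", pc)

    @property
    def cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def cumulative_incident_cases(self) -> float:
        return float(self.new_cases.sum())

    @property
    def person_cycles_depressed(self) -> float:
        return float(self.person_cycles[_DEP])


def run_markov(
    group_size: float,
    quarterly_incidence: float,
    quarterly_recovery: float,
    cycles: int,
    half_cycle: bool = False,
) -> Trajectory:
    """Roll a cohort group forward through the three-state chain.

    Transitions per cycle: well -> depressed with ``quarterly_incidence``,
    depressed -> recovered with ``quarterly_recovery``; recovered absorbs.
    """
    if cycles < 1:
        raise ValueError(f"need at least one cycle, got {cycles}")
    for name, p in (
        ("quarterly_incidence", quarterly_incidence),
        ("quarterly_recovery", quarterly_recovery),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    occ = np.zeros((cycles + 1, 3))
    occ[0, _WELL] = group_size
    new_cases = np.zeros(cycles)
    for c in range(1, cycles + 1):
        well, dep, rec = occ[c - 1]
        onset = well * quarterly_incidence
        recover = dep * quarterly_recovery
        occ[c, _WELL] = well - onset
        occ[c, _DEP] = dep - recover + onset
        occ[c, _REC] = rec + recover
        new_cases[c - 1] = onset
    return Trajectory(
        group_size=float(group_size), occupancy=occ,
        new_cases=new_cases, half_cycle=half_cycle,
    )


@dataclass(frozen=True)
class ArmOutcome:
    """Trajectories of every risk group in one arm, plus programme exposure.

    ``n_programme`` is the expected number of patients who access the
    prevention programme (screen-positives in the targeted arm; uptake x
    cohort in the universal arm); ``n_offered`` the number offered it.
    ``n_screened`` is non-zero only in the targeted arm.
    """

    arm: Arm
    trajectories: dict[str, Trajectory]
    n_screened: float
    n_programme: float
    n_offered: float

    @property
    def incident_cases(self) -> float:
        return sum(t.cumulative_incident_cases for t in self.trajectories.values())


def evaluate_arm(params: ModelParameters, arm: Arm) -> ArmOutcome:
    """Run the decision tree + Markov model for one strategy."""
    n = float(params.cohort_size)
    q_rec = quarterly_recovery_probability(params.recovery_prob_6m)
    cycles = params.horizon_cycles
    hc = params.half_cycle_correction
    scale = params.or_application

    if arm is Arm.PREDICTD:
        strat = stratify_cohort(n, params.annual_incidence, params.screening)
        q_pos = build_cycle_probability(
            strat.high_risk_baseline_12m, params.or_targeted, 1.0, scale
        )
        q_neg = build_cycle_probability(
            strat.low_risk_baseline_12m, 1.0, 1.0, scale
        )
        trajectories = {
            "screen_positive": run_markov(strat.n_positive, q_pos, q_rec, cycles, hc),
            "screen_negative": run_markov(strat.n_negative, q_neg, q_rec, cycles, hc),
        }
        return ArmOutcome(
            arm=arm, trajectories=trajectories, n_screened=n,
            n_programme=strat.n_positive, n_offered=strat.n_positive,
        )

    if arm is Arm.UNIVERSAL:
        q = build_cycle_probability(
            params.annual_incidence, params.or_universal,
            params.universal_uptake, scale,
        )
        trajectories = {"cohort": run_markov(n, q, q_rec, cycles, hc)}
        return ArmOutcome(
            arm=arm, trajectories=trajectories, n_screened=0.0,
            n_programme=n * params.universal_uptake, n_offered=n,
        )

    q = build_cycle_probability(params.annual_incidence, 1.0, 1.0, scale)
    trajectories = {"cohort": run_markov(n, q, q_rec, cycles, hc)}
    return ArmOutcome(
        arm=arm, trajectories=trajectories, n_screened=0.0,
        n_programme=0.0, n_offered=0.0,
    )


def cases_prevented(params: ModelParameters, arm: Arm) -> float:
    """Expected incident cases avoided by ``arm`` relative to TAU."""
    tau = evaluate_arm(params, Arm.TAU).incident_cases
    return tau - evaluate_arm(params, arm).incident_cases


def trajectories_frame(outcome: ArmOutcome) -> pd.DataFrame:
    """Tidy per-cycle occupancies: (cycle, state, arm, group, expected_count)."""
    rows = []
    for group, traj in outcome.trajectories.items():
        for c in range(traj.occupancy.shape[0]):
            for s, state in enumerate(STATES):
                rows.append(
                    {
                        "cycle": c,
                        "state": state,
                        "arm": outcome.arm.value,
                        "group": group,
                        "expected_count": traj.occupancy[c, s],
                    }
                )
    return pd.DataFrame(rows)
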