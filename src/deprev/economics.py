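"""Cost and QALY accounting, net monetary benefit and incremental analysis.

Annual costs and utilities are divided by four so each Markov cycle carries
three months' worth; there is no discounting over the 12-month horizon.
Treatment cost accrues only in the depressed state, for each cycle spent
there (no annual lump sum).  NMB = WTP x QALYs - cost, reported both as a
cohort total and per patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort_model import Arm, ArmOutcome, evaluate_arm
from .parameters import ModelParameters

__all__ = [
    "ArmResult",
    "IncrementalTable",
    "screening_cost",
    "weighted_treatment_cost",
    "arm_economics",
    "model_run",
    "incremental_analysis",
    "results_frame",
]

CYCLES_PER_YEAR = 4.0


def screening_cost(
    n: float,
    minutes_per_patient: float,
    nurse_cost_per_hour: float,
    training_cost: float,
) -> float:
    """Cost of administering the risk score to ``n`` patients plus training."""
    if min(n, minutes_per_patient, nurse_cost_per_hour, training_cost) < 0:
        raise ValueError("screening cost inputs must be non-negative")
    return n * (minutes_per_patient / 60.0) * nurse_cost_per_hour + training_cost


def weighted_treatment_cost(mix: Iterable[tuple[float, float]]) -> float:
    """Weighted average annual treatment cost from a (proportion, cost) mix.

    Proportions may sum to less than 1; the remainder receives no treatment
    at zero cost.
    """
    total_prop = 0.0
    total = 0.0
    for prop, cost in mix:
        if prop < 0 or cost < 0:
            raise ValueError("proportions and costs must be non-negative")
        total_prop += prop
        total += prop * cost
    if total_prop > 1.0 + 1e-12:
        raise ValueError(f"treatment-mix proportions sum to {total_prop} > 1")
    return total


@dataclass(frozen=True)
class ArmResult:
    """Totals for one strategy arm at a stated willingness to pay."""

    arm: Arm
    cost_screening: float
    cost_programme: float
    cost_treatment: float
    total_qalys: float
    incident_cases: float
    wtp: float
    cohort_size: float

    @property
    def total_cost(self) -> float:
        return self.cost_screening + self.cost_programme + self.cost_treatment

    @property
    def nmb(self) -> float:
        return self.wtp * self.total_qalys - self.total_cost

    @property
    def per_patient_nmb(self) -> float:
        return self.nmb / self.cohort_size


def arm_economics(
    outcome: ArmOutcome,
    params: ModelParameters,
    universal_cost_scales_with_uptake: bool = True,
) -> ArmResult:
    """Cost and QALY totals for one evaluated arm.

    QALYs sum ``person_cycles x utility / 4`` over states and groups;
    treatment cost is ``person_cycles_depressed x annual_treatment_cost /
    4``.  Programme cost covers patients who access it; in the universal
    arm the documented switch charges all offered patients instead.
    """
    utilities = np.array(
        [params.utility_well, params.utility_depressed, params.utility_recovered]
    )
    qalys = 0.0
    dep_cycles = 0.0
    for traj in outcome.trajectories.values():
        qalys += float(traj.person_cycles @ utilities) / CYCLES_PER_YEAR
        dep_cycles += traj.person_cycles_depressed
    cost_treatment = dep_cycles * params.annual_treatment_cost / CYCLES_PER_YEAR

    if outcome.arm is Arm.PREDICTD:
        cost_screen = screening_cost(
            outcome.n_screened,
            params.nurse_minutes_per_patient,
            params.nurse_cost_per_hour,
            params.training_cost,
        )
    else:
        cost_screen = 0.0

    n_charged = outcome.n_programme
    if outcome.arm is Arm.UNIVERSAL and not universal_cost_scales_with_uptake:
        n_charged = outcome.n_offered
    cost_programme = n_charged * params.programme_cost_per_patient

    return ArmResult(
        arm=outcome.arm,
        cost_screening=cost_screen,
        cost_programme=cost_programme,
        cost_treatment=cost_treatment,
        total_qalys=qalys,
        incident_cases=outcome.incident_cases,
        wtp=params.wtp,
        cohort_size=float(params.cohort_size),
    )


def model_run(
    params: ModelParameters,
    universal_cost_scales_with_uptake: bool = True,
) -> dict[Arm, ArmResult]:
    """Deterministic evaluation of all three arms for one parameter set."""
    return {
        arm: arm_economics(
            evaluate_arm(params, arm), params, universal_cost_scales_with_uptake
        )
        for arm in Arm
    }


@dataclass(frozen=True)
class IncrementalTable:
    """Cross-arm comparison: increments vs TAU, dominance, optimal arm."""

    frame: pd.DataFrame
    optimal_arm: Arm

    def strongly_dominated(self, arm: Arm) -> bool:
        return bool(self.frame.loc[arm.value, "strongly_dominated"])


def incremental_analysis(
    results: Mapping[Arm, ArmResult], wtp: float | None = None
) -> IncrementalTable:
    """Incremental costs/QALYs vs TAU with strong-dominance flags.

    An arm is strongly dominated iff some other arm has strictly lower cost
    and strictly higher QALYs.  The optimal arm maximises NMB at ``wtp``
    (defaults to the WTP the results were computed at).
    """
    if set(results) != set(Arm):
        raise ValueError("incremental analysis needs all three arms")
    wtp = results[Arm.TAU].wtp if wtp is None else wtp
    tau = results[Arm.TAU]
    rows = {}
    for arm, res in results.items():
        dominated = any(
            other.total_cost < res.total_cost and other.total_qalys > res.total_qalys
            for o_arm, other in results.items()
            if o_arm is not arm
        )
        nmb = wtp * res.total_qalys - res.total_cost
        rows[arm.value] = {
            "total_cost": res.total_cost,
            "total_qalys": res.total_qalys,
            "incident_cases": res.incident_cases,
            "incremental_cost_vs_tau": res.total_cost - tau.total_cost,
            "incremental_qalys_vs_tau": res.total_qalys - tau.total_qalys,
            "nmb": nmb,
            "per_patient_nmb": nmb / res.cohort_size,
            "strongly_dominated": dominated,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "arm"
    optimal = max(results, key=lambda a: wtp * results[a].total_qalys - results[a].total_cost)
    return IncrementalTable(frame=frame, optimal_arm=optimal)


def results_frame(results: Mapping[Arm, ArmResult]) -> pd.DataFrame:
    """One row per arm with cost components, QALYs, cases and NMB."""
    rows = {}
    for arm, res in results.items():
        rows[arm.value] = {
            "cost_screening": res.cost_screening,
            "cost_programme": res.cost_programme,
            "cost_treatment": res.cost_treatment,
            "total_cost": res.total_cost,
            "total_qalys": res.total_qalys,
            "incident_cases": res.incident_cases,
            "nmb": res.nmb,
            "per_patient_nmb": res.per_patient_nmb,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "arm"
    return frame
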