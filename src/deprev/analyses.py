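"""Scenario and threshold analyses over the base-case model.

Covers: named odds-ratio scenarios (GP-recruited studies, interpersonal
therapy, everything-but-IP), risk-score threshold variants, the maximum
affordable programme cost as a function of the odds ratio (bisection
replacing a spreadsheet goal-seek), a universal-uptake sweep, and a paired
comparison with and without the half-cycle correction.  Paired analyses use
common random numbers: the same seeded draws are re-evaluated under each
variant, so differences are free of between-variant Monte Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_model import Arm, evaluate_arm, stratify_cohort
from .economics import arm_economics, incremental_analysis, model_run, IncrementalTable
from .parameters import DistributionSpec, ModelParameters, ParameterSetWithUncertainty
from .psa import ARM_ORDER, Ceac, PsaResult, ceac, run_psa, sample_draw

__all__ = [
    "Scenario",
    "SCENARIO_PRESETS",
    "apply_scenario",
    "ScenarioResult",
    "run_scenario",
    "MaxCostResult",
    "max_affordable_cost",
    "max_cost_curve",
    "uptake_sweep",
    "crossover_uptake",
    "HalfCycleComparison",
    "half_cycle_comparison",
]


@dataclass(frozen=True)
class Scenario:
    """A labelled set of overrides applied on top of a parameter set.

    ``overrides`` replace point values (re-centring any matching
    distribution while preserving its spread); ``dist_overrides`` replace
    whole distribution specs, e.g. an alternative odds ratio with its own
    CI.
    """

    label: str
    overrides: dict = field(default_factory=dict)
    dist_overrides: dict = field(default_factory=dict)


#: Alternative effect estimates and screening thresholds from the source
#: evidence base.
SCENARIO_PRESETS: dict[str, Scenario] = {
    "gp_only": Scenario(
        label="gp_only",
        dist_overrides={
            "or_targeted": DistributionSpec(
                family="lognormal", mean=0.6, ci_low=0.3, ci_high=1.2,
                source="pooled OR of the two GP-recruited prevention studies",
            )
        },
    ),
    "ip": Scenario(
        label="ip",
        dist_overrides={
            "or_targeted": DistributionSpec(
                family="lognormal", mean=0.13, ci_low=0.04, ci_high=0.42,
                source="OR of interpersonal-therapy prevention studies",
            )
        },
    ),
    "non_ip": Scenario(
        label="non_ip",
        dist_overrides={
            "or_targeted": DistributionSpec(
                family="lognormal", mean=0.75, ci_low=0.58, ci_high=0.98,
                source="pooled OR excluding interpersonal-therapy studies",
            )
        },
    ),
    "threshold_0154": Scenario(
        label="threshold_0154",
        overrides={"sensitivity": 0.458, "specificity": 0.85, "threshold_label": 0.154},
    ),
    "threshold_0183": Scenario(
        label="threshold_0183",
        overrides={"sensitivity": 0.373, "specificity": 0.9, "threshold_label": 0.183},
    ),
}


def apply_scenario(
    spec: ParameterSetWithUncertainty, scenario: Scenario
) -> ParameterSetWithUncertainty:
    out = spec.with_point_updates(**scenario.overrides)
    for name, dist in scenario.dist_overrides.items():
        out = out.with_dist(name, dist)
    return out


@dataclass(frozen=True)
class ScenarioResult:
    label: str
    point_results: dict
    incremental: IncrementalTable
    psa: PsaResult
    ceac: Ceac

    def mean_cases_prevented(self, arm: Arm = Arm.PREDICTD) -> float:
        return self.psa.mean_cases_prevented(arm)

    def point_cases_prevented(self, arm: Arm = Arm.PREDICTD) -> float:
        return (
            self.point_results[Arm.TAU].incident_cases
            - self.point_results[arm].incident_cases
        )


def run_scenario(
    spec: ParameterSetWithUncertainty,
    scenario: Scenario,
    n_sims: int = 10000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
) -> ScenarioResult:
    """Full pipeline (point run, PSA, CEAC) under a scenario's overrides."""
    sc_spec = apply_scenario(spec, scenario)
    point_results = model_run(sc_spec.point)
    incremental = incremental_analysis(point_results)
    psa_res = run_psa(sc_spec, n_sims=n_sims, seed=seed)
    curves = ceac(psa_res, wtp_grid)
    return ScenarioResult(
        label=scenario.label,
        point_results=point_results,
        incremental=incremental,
        psa=psa_res,
        ceac=curves,
    )


@dataclass(frozen=True)
class MaxCostResult:
    """Root of the break-even programme-cost equation for one odds ratio."""

    odds_ratio: float
    max_cost: float
    status: str  # "ok" | "infeasible" | "unbounded"
    f_at_root: float
    reps: int


def _draw_components(
    spec: ParameterSetWithUncertainty,
    or_value: float,
    wtp: float,
    reps: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-draw (NMB of targeted arm at zero programme cost, number of
    screen-positives, best competitor NMB) with the targeted OR held fixed."""
    or_eff = max(or_value, 1e-9)
    fixed = spec.with_dist(
        "or_targeted", DistributionSpec(family="fixed", mean=or_eff)
    )
    rng = np.random.default_rng(seed)
    nmb_pd0 = np.empty(reps)
    n_pos = np.empty(reps)
    best_other = np.empty(reps)
    for i in range(reps):
        draw = sample_draw(fixed, rng)
        prog_cost = draw.programme_cost_per_patient
        zero = draw.with_updates(programme_cost_per_patient=0.0)
        results = model_run(zero)
        strat = stratify_cohort(
            zero.cohort_size, zero.annual_incidence, zero.screening
        )
        n_pos[i] = strat.n_positive
        pd_res = results[Arm.PREDICTD]
        nmb_pd0[i] = wtp * pd_res.total_qalys - pd_res.total_cost
        uni = results[Arm.UNIVERSAL]
        uni_cost = uni.total_cost + (
            zero.cohort_size * zero.universal_uptake * prog_cost
        )
        nmb_uni = wtp * uni.total_qalys - uni_cost
        tau = results[Arm.TAU]
        nmb_tau = wtp * tau.total_qalys - tau.total_cost
        best_other[i] = max(nmb_uni, nmb_tau)
    return nmb_pd0, n_pos, best_other


def max_affordable_cost(
    spec: ParameterSetWithUncertainty,
    or_value: float,
    wtp: float = 20000.0,
    reps: int = 100,
    seed: int = 0,
    bracket: tuple[float, float] = (-500.0, 1000.0),
    tol: float = 0.01,
) -> MaxCostResult:
    """Highest per-patient programme cost at which the targeted arm stays
    optimal at ``wtp``, for a fixed odds ratio.

    Finds the root of ``f(c) = mean NMB_targeted(c) - mean max(NMB_tau,
    NMB_universal)`` over ``reps`` seeded PSA draws by bisection on the
    bracket; ``f`` is averaged over draws first, so the root is the
    break-even cost of the expected NMB difference.  A bracket with no sign
    change is reported as infeasible (f < 0 everywhere: even a negative
    cost cannot rescue the arm) or unbounded (f > 0 at the upper end).
    """
    if reps < 1:
        raise ValueError(f"need at least one repetition, got {reps}")
    nmb_pd0, n_pos, best_other = _draw_components(spec, or_value, wtp, reps, seed)
    base = float(np.mean(nmb_pd0 - best_other))
    slope = float(np.mean(n_pos))

    def f(c: float) -> float:
        return base - slope * c

    lo, hi = bracket
    f_lo, f_hi = f(lo), f(hi)
    if f_lo < 0.0:
        return MaxCostResult(or_value, lo, "infeasible", f_lo, reps)
    if f_hi > 0.0:
        return MaxCostResult(or_value, hi, "unbounded", f_hi, reps)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid) < tol:
            return MaxCostResult(or_value, mid, "ok", f_mid, reps)
        if f_mid > 0.0:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    return MaxCostResult(or_value, mid, "ok", f(mid), reps)


def max_cost_curve(
    spec: ParameterSetWithUncertainty,
    or_grid: np.ndarray | None = None,
    wtp: float = 20000.0,
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Maximum affordable programme cost across an odds-ratio grid.

    Default grid 0 to 1 in steps of 0.01.  The same seed (hence the same
    draws of all other parameters) is used at every grid point, so the
    curve is monotone non-increasing in the odds ratio by construction.
    """
    grid = np.round(np.arange(0.0, 1.0001, 0.01), 2) if or_grid is None else np.asarray(or_grid)
    rows = []
    for or_value in grid:
        res = max_affordable_cost(spec, float(or_value), wtp, reps, seed)
        rows.append(
            {
                "odds_ratio": float(or_value),
                "max_cost": res.max_cost,
                "status": res.status,
                "reps": reps,
            }
        )
    return pd.DataFrame(rows)


def _universal_nmb(
    draw: ModelParameters,
    uptake: float,
    wtp: float,
    effect_scales_with_uptake: bool,
    cost_scales_with_uptake: bool,
) -> float:
    effect_uptake = uptake if effect_scales_with_uptake else 1.0
    params_u = draw.with_updates(universal_uptake=effect_uptake)
    outcome = evaluate_arm(params_u, Arm.UNIVERSAL)
    res = arm_economics(outcome, params_u)
    cost_uptake = uptake if cost_scales_with_uptake else 1.0
    cost = res.cost_treatment + (
        draw.cohort_size * cost_uptake * draw.programme_cost_per_patient
    )
    return wtp * res.total_qalys - cost


def uptake_sweep(
    spec: ParameterSetWithUncertainty,
    percent_grid: np.ndarray | None = None,
    reps: int = 100,
    seed: int = 0,
    wtp: float = 20000.0,
    effect_scales_with_uptake: bool = True,
    cost_scales_with_uptake: bool = True,
) -> pd.DataFrame:
    """Probability each arm is optimal as universal uptake varies.

    Uses common random numbers: the targeted and TAU arms are evaluated
    once per draw and reused at every uptake value.  By default both the
    universal programme's effect and its cost scale with uptake; the
    switches expose the alternative conventions.
    """
    grid = np.arange(0, 101) if percent_grid is None else np.asarray(percent_grid)
    rng = np.random.default_rng(seed)
    draws = [sample_draw(spec, rng) for _ in range(reps)]
    nmb_fixed = np.empty((reps, 2))  # predictd, tau
    for i, draw in enumerate(draws):
        results = model_run(draw)
        for j, arm in enumerate((Arm.PREDICTD, Arm.TAU)):
            res = results[arm]
            nmb_fixed[i, j] = wtp * res.total_qalys - res.total_cost
    rows = []
    for pct in grid:
        uptake = float(pct) / 100.0
        nmb = np.empty((reps, 3))  # predictd, universal, tau
        nmb[:, 0] = nmb_fixed[:, 0]
        nmb[:, 2] = nmb_fixed[:, 1]
        for i, draw in enumerate(draws):
            nmb[:, 1][i] = _universal_nmb(
                draw, uptake, wtp, effect_scales_with_uptake, cost_scales_with_uptake
            )
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb >= best - 1e-9 * np.maximum(1.0, np.abs(best))
        weights = winners / winners.sum(axis=1, keepdims=True)
        probs = weights.mean(axis=0)
        rows.append(
            {
                "uptake_percent": float(pct),
                "prob_predictd_optimal": probs[0],
                "prob_universal_optimal": probs[1],
                "prob_tau_optimal": probs[2],
            }
        )
    return pd.DataFrame(rows)


def crossover_uptake(
    spec: ParameterSetWithUncertainty,
    reps: int = 100,
    seed: int = 0,
    wtp: float = 20000.0,
    effect_scales_with_uptake: bool = True,
    cost_scales_with_uptake: bool = True,
    tol: float = 0.5,
) -> float | None:
    """Uptake percentage below which the universal arm is the modal choice.

    Bisects ``g(u) = P(universal optimal) - P(targeted optimal)`` on
    [0, 100] with common random numbers.  Returns None when the universal
    arm is never ahead (no crossover exists).
    """

    def g(pct: float) -> float:
        row = uptake_sweep(
            spec, np.array([pct]), reps, seed, wtp,
            effect_scales_with_uptake, cost_scales_with_uptake,
        ).iloc[0]
        return row["prob_universal_optimal"] - row["prob_predictd_optimal"]

    lo, hi = 0.0, 100.0
    g_lo, g_hi = g(lo), g(hi)
    if g_lo <= 0.0:
        return None
    if g_hi > 0.0:
        return 100.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if g(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class HalfCycleComparison:
    """Paired PSA results with and without the half-cycle correction.

    Arrays are per draw and per arm, computed from identical parameter
    draws (common random numbers).
    """

    n_sims: int
    seed: int
    wtp: float
    treatment_cost_base: dict
    treatment_cost_corrected: dict
    qalys_base: dict
    qalys_corrected: dict
    nmb_base: dict
    nmb_corrected: dict

    def summary(self) -> pd.DataFrame:
        rows = {}
        for arm in ARM_ORDER:
            rows[arm.value] = {
                "mean_nmb_base": self.nmb_base[arm].mean(),
                "mean_nmb_corrected": self.nmb_corrected[arm].mean(),
                "mean_nmb_delta": (self.nmb_corrected[arm] - self.nmb_base[arm]).mean(),
                "mean_qaly_delta": (
                    self.qalys_corrected[arm] - self.qalys_base[arm]
                ).mean(),
                "mean_treatment_cost_delta": (
                    self.treatment_cost_corrected[arm] - self.treatment_cost_base[arm]
                ).mean(),
            }
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index.name = "arm"
        return frame


def half_cycle_comparison(
    spec: ParameterSetWithUncertainty,
    n_sims: int = 1000,
    seed: int = 0,
    wtp: float | None = None,
) -> HalfCycleComparison:
    """Evaluate identical draws with the half-cycle correction off and on."""
    wtp = spec.point.wtp if wtp is None else wtp
    rng = np.random.default_rng(seed)
    shape = n_sims
    out = {
        key: {arm: np.empty(shape) for arm in ARM_ORDER}
        for key in ("tc_b", "tc_c", "q_b", "q_c", "n_b", "n_c")
    }
    for i in range(n_sims):
        draw = sample_draw(spec, rng)
        for flag, suffix in ((False, "b"), (True, "c")):
            results = model_run(draw.with_updates(half_cycle_correction=flag))
            for arm in ARM_ORDER:
                res = results[arm]
                out[f"tc_{suffix}"][arm][i] = res.cost_treatment
                out[f"q_{suffix}"][arm][i] = res.total_qalys
                out[f"n_{suffix}"][arm][i] = wtp * res.total_qalys - res.total_cost
    return HalfCycleComparison(
        n_sims=n_sims,
        seed=seed,
        wtp=wtp,
        treatment_cost_base=out["tc_b"],
        treatment_cost_corrected=out["tc_c"],
        qalys_base=out["q_b"],
        qalys_corrected=out["q_c"],
        nmb_base=out["n_b"],
        nmb_corrected=out["n_c"],
    )
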