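"""Universal-programme uptake sweep, 0-100% in 1-point steps.

Re-evaluates the universal arm at each uptake level with common random
numbers (100 PSA repetitions) and reports the probability each arm is
optimal at WTP GBP 20,000/QALY.  By default both the universal programme's
effect and its cost scale with uptake; --cost-only-scaling reproduces the
alternative convention in which all patients receive the effect but only
those accessing the programme are costed.
"""

import argparse
from pathlib import Path

from deprev.analyses import crossover_uptake, uptake_sweep
from deprev.parameters import reference_fixture


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--reps", type=int, default=100)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--cost-only-scaling", action="store_true")
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fixture = reference_fixture()
    effect_scales = not args.cost_only_scaling
    sweep = uptake_sweep(
        fixture, reps=args.reps, seed=args.seed,
        effect_scales_with_uptake=effect_scales,
    )
    name = "uptake_sweep_cost_only.csv" if args.cost_only_scaling else "uptake_sweep.csv"
    sweep.to_csv(args.out / name, index=False)
    cross = crossover_uptake(
        fixture, reps=args.reps, seed=args.seed,
        effect_scales_with_uptake=effect_scales,
    )
    if cross is None:
        print("universal prevention is never the modal optimal choice")
    else:
        print(f"universal prevention is the modal choice below ~{cross:.0f}% uptake")
    lead = sweep["prob_universal_optimal"] > sweep["prob_predictd_optimal"]
    print(f"grid points where universal leads: {int(lead.sum())} of {len(sweep)}")
    print(f"sweep written to {args.out}/{name}")


if __name__ == "__main__":
    main()
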