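# deprev — cost-effectiveness of depression prevention in primary care

`deprev` is a decision-analytic model for health economists and mental-health
researchers asking: **is it worth screening general-practice attenders with a
depression risk algorithm and offering those at high risk a low-intensity
prevention programme?** It compares three strategies over 12 months from a
health-service perspective:

* **targeted prevention** — a nurse-administered risk score; patients above
  the threshold are offered a prevention programme (e.g. computerised CBT,
  bibliotherapy);
* **universal prevention** — the programme is offered to everyone, no
  screening;
* **treatment as usual (TAU)** — incident cases receive usual GP care.

A decision tree splits each 1000-patient cohort by screening result
(TP = n·π·Se, FP = n·(1−π)·(1−Sp), …), and each group moves through a
three-state Markov model — *no major depression* → *depressed* → *recovered*
— in four quarterly cycles, with probabilities converted between horizons via
the constant-hazard pair r = −ln(1−p)/t, p = 1 − e^(−rt). Prevention acts on
a group's baseline risk through an odds ratio. Outcomes are incident cases,
costs, QALYs and net monetary benefit NMB = λ·QALYs − cost; parameter
uncertainty is propagated by probabilistic sensitivity analysis (beta /
gamma / log-normal families) and summarised as cost-effectiveness
acceptability curves. See `docs/methods.md` for the full model description
and every assumed parameter.

## Worked example

```python
from deprev import reference_fixture, model_run, cases_prevented, run_psa, ceac
from deprev.cohort_model import Arm
from deprev.economics import results_frame

fixture = reference_fixture()           # canonical parameter set
print(results_frame(model_run(fixture.point)).round(2))

res = run_psa(fixture, n_sims=10000, seed=1)
print(round(res.mean_cases_prevented(Arm.PREDICTD), 2))
print(ceac(res).modal_arm(20000.0))
```

The deterministic run prints (abridged):

```
                      total_cost  total_qalys  incident_cases  per_patient_nmb
predictd_prevention     48914.90       848.75           72.86         16926.08
universal_prevention   115056.08       847.66           79.99         16838.11
tau                     16575.76       846.41           88.00         16911.62
```

Reading this: under TAU, 88 of 1000 patients develop depression within the
year. Targeted prevention averts 15.14 of those cases (88 − 72.86), costs
£32,339 more than TAU, gains 2.3 QALYs, and has the highest per-patient NMB
at £20,000/QALY. Universal prevention averts 8 cases for £98,480 more than
TAU — less health gain at greater cost than the targeted strategy, so it is
strongly dominated. The PSA mean cases prevented is ≈ 15.0 and the targeted
arm is the modal optimal choice at £20,000/QALY (probability ≈ 0.74).

## Analysis scripts

Numbered drivers under `analysis/` rerun every published analysis and write
tables to `results/`:

| script | what it does |
|---|---|
| `01_base_case.py` | deterministic three-arm run, incremental table, trajectories |
| `02_psa_ceac.py` | 10,000-draw PSA and acceptability curves |
| `03_scenarios.py` | alternative ORs (GP-recruited 0.6, interpersonal therapy 0.13, non-IP 0.75) and screen thresholds (0.154, 0.183) |
| `04_max_cost_curve.py` | maximum affordable programme cost by OR (bisection, 100 reps/point) |
| `05_uptake_sweep.py` | universal-uptake sweep 0–100% with common random numbers |
| `06_half_cycle.py` | half-cycle-correction comparison on paired draws |

All accept `--seed`, and `--sims`/`--reps` where relevant. Parameter sets
round-trip through YAML (`save_parameters` / `load_parameters`); every
assumed (non-published) value is flagged `assumed: true` in the file and
listed at the start of `01_base_case.py` output.

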