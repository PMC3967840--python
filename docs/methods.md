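# Methods

## The model

`deprev` implements a decision-analytic cost-effectiveness model of
depression prevention for adult primary-care attenders with no current
depression diagnosis, from a health-service (NHS) perspective over a
12-month horizon. Three strategies are compared on a cohort of 1000
patients per arm:

1. **Targeted prevention** — every patient completes a validated
   depression risk score administered by a practice nurse; those above the
   score threshold are directed to a low-intensity prevention programme
   (e.g. computerised CBT, bibliotherapy, group therapy).
2. **Universal prevention** — the whole cohort is offered the programme
   with no risk assessment.
3. **Treatment as usual (TAU)** — no screening, no prevention; incident
   cases receive usual GP care.

A decision tree stratifies the targeted arm into expected true/false
positive/negative counts from the cohort incidence π, sensitivity Se and
specificity Sp:

    TP = n·π·Se,  FN = n·π·(1−Se),  FP = n·(1−π)·(1−Sp),  TN = n·(1−π)·Sp

The screen-positive group's baseline 12-month risk is the positive
predictive value TP/(TP+FP); the screen-negative group's is FN/(TN+FN).
Each group is then rolled through a three-state Markov cohort model —
*no major depression* → *depressed* → *recovered* — in four 3-month
cycles. Arrows are one-directional: recovery absorbs over this horizon
(no relapse within 12 months) and there is no death state. Accounting is
in expected fractional patients; rounding happens only at reporting.

Probabilities are converted between horizons through the constant-hazard
representation, r = −ln(1−p)/t and p = 1 − exp(−rt), so an annual risk
decomposed into four quarterly cycles compounds back to itself exactly.
The 6-month recovery probability (0.50 by assumption, see below) becomes a
quarterly transition the same way.

### Applying the prevention effect

Prevention effectiveness enters as an odds ratio (OR) against the baseline
risk of the group receiving the programme. Two application conventions are
implemented, selected by `ModelParameters.or_application`:

* `"risk"` (default): treated risk = baseline × OR. This is the
  convention many spreadsheet models use in practice, and it is the one
  that reproduces this model's published anchor outputs (15/14/11 cases
  prevented across screen thresholds; the £160 and £75 maximum-cost
  figures). With a screen-positive baseline near 0.196 the two conventions
  differ materially, so the default matters.
* `"odds"`: treated risk = OR·ω/(1+OR·ω) with ω the baseline odds — the
  textbook conversion, exposed by `epi_math.apply_odds_ratio` and
  available as a switch.

The uptake-weighted mixture `u·treated + (1−u)·baseline` is formed on the
12-month risk scale and then decomposed into a constant quarterly
probability (a per-cycle application variant exists behind the
`per_cycle` flag; the 12-month default is used throughout).

### Outcomes and economics

Annual utilities and costs are divided by four so each cycle carries three
months' worth; nothing is discounted over the 12-month horizon. QALYs sum
state person-cycles × utility/4 over groups; treatment cost accrues only
in the depressed state, quarterly, for as long as a patient stays there
(no annual lump sum). Screening cost is n·(minutes/60)·hourly-rate plus a
fixed training cost, charged only in the targeted arm; programme cost is
charged per patient accessing the programme (screen-positives in the
targeted arm, uptake × cohort in the universal arm — a documented switch
charges all offered patients instead). Net monetary benefit is
NMB = λ·QALYs − cost at willingness to pay λ (headline £20,000/QALY),
reported as a cohort total and per patient. An arm is strongly dominated
when another arm has strictly lower cost and strictly higher QALYs.

**Half-cycle correction** (off by default, matching the base case):
patients entering the depressed state contribute half of their entry cycle
to *depressed* and the other half to *no major depression*, reducing
depressed person-cycles by 0.5 × incident cases. The correction therefore
lowers treatment cost and raises QALYs for every draw, by construction.
Transitions into *recovered* are not half-cycled; the correction targets
the state that carries costs and disutility.

## Parameters

The reference fixture (`deprev.parameters.reference_fixture`) uses the
published point estimates verbatim: annual incidence 0.088; Se 0.506 / Sp
0.8 at the base score threshold 0.133 (0.458/0.85 at 0.154 and 0.373/0.9
at 0.183 as scenarios); targeted-programme OR 0.66; programme cost mean
£100 (gamma, SE £50, placing ~95% of mass in the quoted £0–£200 range);
£2,000 training; 15 nurse-minutes per screen; utility 0.86 when well;
cohort 1000; four cycles; WTP £20,000/QALY; universal uptake 1.

Quantities the underlying study sourced from references without printing
are **assumptions**, flagged `assumed: true` in serialized parameter files
and logged by `analysis/01_base_case.py`:

| parameter | value | rationale |
|---|---|---|
| recovery_prob_6m | 0.50 | plausible 6-month remission under usual care |
| utility_depressed / utility_recovered | 0.58 / 0.72 | typical UK EQ-5D levels for current and remitted depression |
| annual_treatment_cost | £400 | weighted average over prescription / psychological / secondary-care / no-treatment mix |
| nurse_cost_per_hour | £42 | GP-nurse unit cost, 2010/11 price level |
| or_universal | 0.909 | calibrated so the universal arm prevents 8 of the 88 expected cases under the default risk-scale application |
| or_targeted 95% CI | (0.552, 0.790) | log-scale spread borrowed from the precision of the source meta-analysis pooled estimate |
| or_universal 95% CI | (0.65, 1.27) | wide: only two universal-prevention studies inform it |
| SEs for incidence, Se/Sp, recovery, utilities | 0.009 / 0.05, 0.015 / 0.05 / 0.02–0.05 | binomial-precision-scale assumptions |

Where an SE is genuinely unreported the SE=mean rule applies (annual
treatment cost: gamma with shape 1). That rule is moment-infeasible for
beta-distributed parameters with mean above ½, which is why utilities and
probabilities carry explicit assumed SEs instead.

## Probabilistic sensitivity analysis

Each uncertain parameter is sampled independently from its fitted family —
beta by method of moments for probabilities and utilities, gamma
(shape = mean²/SE², scale = SE²/mean) for costs, log-normal with
μ = ln(OR) and σ = (ln hi − ln lo)/(2·1.96) for odds ratios (the OR is the
distribution's median, the usual convention). One RNG stream is consumed
in parameter-name-sorted order so a seed pins the whole analysis. Draws
violating the joint invariants (mainly the utility ordering
depressed ≤ recovered ≤ well, ~3% of draws at the fixture's SEs) are
rejected and redrawn; this truncates the tails slightly and is accepted as
the price of guaranteeing every evaluated draw is a valid parameter set.
The default is 10,000 simulations; the test suite runs PSA-based checks at
1,000 draws.

CEACs report, per WTP on a £0–£50,000 grid, the fraction of draws in which
each arm attains the highest NMB; exact ties are split evenly so the three
probabilities always sum to 1.

## Scenario machinery and numerical choices

* **Maximum affordable programme cost**: for a fixed OR, the break-even
  cost solves f(c) = E[NMB_targeted(c)] − E[max(NMB_TAU, NMB_universal)] = 0
  over seeded PSA draws. Because NMB is linear in c the draws are
  evaluated once at c = 0 and bisection on [−£500, £1000] drives |f| below
  £0.01; a bracket with f < 0 everywhere is reported infeasible (even a
  free programme cannot make the arm optimal). The same seed — hence the
  same draws — is reused across the OR grid, making the curve monotone
  non-increasing by construction.
* **Uptake sweep**: common random numbers across uptake values; the
  targeted and TAU arms are evaluated once per draw. The default scales
  both the universal programme's effect and its cost with uptake. The
  alternative convention (`effect_scales_with_uptake=False`: everyone
  receives the effect, only accessors are costed) is exposed because it is
  the only mechanism under which universal prevention can lead at low
  uptake — under it the crossover sits near 17% uptake, while under the
  default the universal arm never overtakes the targeted arm and the
  crossover is reported as `None`.
* **Half-cycle comparison** uses common random numbers so the
  cost-decrease/QALY-increase directions hold draw by draw, not just in
  expectation.
* Degenerate inputs: a perfect screen gives the positive group a baseline
  risk of exactly 1, which has no finite hazard; effective 12-month risks
  are clamped to 1 − 1e−12 before decomposition. 2×2 tables with zero
  cells receive the Haldane–Anscombe 0.5 correction, flagged in the
  result.

## What the synthetic generator does and does not emulate

`random_parameter_set` produces structurally valid parameter sets across
wide plausible ranges (incidence 2–25%, OR 0.3–1.6, utilities ordered,
costs positive) for property and round-trip testing. It emulates the
*shape* of a real input table — point estimate, SE/CI, distribution family
per parameter — not any real population: passing tests demonstrate the
engine's arithmetic, conservation and monotonicity properties, not that
the fixture's assumed values are externally accurate. Real applications
should replace the assumed entries with study-specific estimates via the
YAML parameter files.

## Known limitations

* Parameters are sampled independently; no correlation structure (e.g.
  between sensitivity and specificity across thresholds) is modelled.
* The 12-month horizon ignores any persistence of the prevention effect;
  if effects persist, cost-effectiveness is understated.
* No relapse, no mortality, no societal costs or productivity losses.
* The headline cohort cost totals depend on the assumed treatment-cost and
  utility inputs; they are magnitude anchors (tens of thousands of pounds
  incremental per 1000 patients), not calibrated reproductions.
* Problem sizes in the shipped analyses (10,000 PSA draws; 100 repetitions
  per grid point in the OR and uptake sweeps) follow the analysis design
  this model was built to replicate; the test suite uses 1,000 draws.
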