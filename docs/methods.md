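# Methods

## Model

`rootcea` implements a tooth-level Markov state-transition model for the
cost-effectiveness of regular 5% sodium-fluoride varnish application
against no preventive intervention in a 60-year-old with 23 remaining
teeth, followed for 20 annual cycles from the perspective of the Chinese
public healthcare system.

Each tooth moves independently through five states:

```
INTACT --p_car--> UNTREATED_CARIES --p_fill--> FILLED --(p_fail: refill, stays FILLED)
                        |    \--within p_fill: p_endo --> endo; p_endo*p_crown --> CROWNED
                        \--p_ext--> EXTRACTED
```

`INTACT` means *never carious*; fluoride varnish acts only on the onset
probability, multiplying `p_car` by a risk ratio `rr = 0.396`. Within a
cycle, new onsets join previously untreated caries in an "active" pool
that resolves into restoration (with an endodontic and crown sub-tree),
extraction, or remaining untreated. `CROWNED` and `EXTRACTED` are
absorbing with zero further cost: secondary caries on restorations, crown
failure and prosthetic replacement are deliberately out of model scope,
as is tooth loss from periodontal disease or trauma. Endodontically
treated teeth that do not receive a crown enter `FILLED` and carry the
refill risk thereafter; refills do not re-enter the endo/crown sub-tree.
Transition probabilities are constant over the horizon (no age
dependence).

The effect unit is the **discounted root-caries-free tooth year**: a
tooth intact at the end of cycle `t` contributes `(1+r)^-t`, so a subject
free of root caries for 20 undiscounted years scores 460 tooth years.
Because a tooth stays intact with probability `(1-p)^t`, the expected
effect has the closed form

```
E = N * sum_{t=1..T} ((1-p)/(1+r))^t
```

which the engine must match to 1e-9 (`closed_form_effect` is the test
oracle). This end-of-cycle convention is the only one that reproduces the
published effectiveness totals (269.46 and 279.67 tooth years), so it is
fixed, not configurable.

## Parameters

Annual per-tooth probabilities (base case): onset 0.007, restoration
0.096, endodontic share 0.268, crown share 0.640, extraction 0.088,
restoration failure 0.079; varnish risk ratio 0.396. Unit costs (2023
CNY): varnish 8 per tooth per year, filling 214, extraction 219.66,
endodontic episode 1468.06 (includes its own filling items), crown 3204.
Settings: 23 teeth, 20 cycles, 5% annual discount on costs and effects,
willingness-to-pay ¥214 per root-caries-free tooth year (the price of one
filling), PPP conversion 3.92 CNY/USD. One-way bounds are the source 95%
CIs for cohort-derived probabilities, source min/max for the two
literature-derived conditional probabilities, itemised fee-schedule
extremes for costs, ±20% for varnish, and 0–8% for the discount rate.

Probabilities estimated from multi-year observation intervals are
converted with the constant-hazard formula `p_annual = 1-(1-p_interval)^(1/n)`
(`annualize`), exposed as a utility: conversion happens during parameter
derivation, never inside the cycle loop.

## Cycle-accrual conventions and cost calibration

The published description fixes the event tree and the effect convention
but not the cost-accrual timing. Those degrees of freedom are isolated in
`CycleConventions`: treatment-cost discount timing (start/end of cycle),
whether restorations placed in a cycle are already at refill risk that
cycle, whether varnish is charged for all 23 positions or only teeth not
yet extracted, varnish discount timing, and an optional half-cycle
correction (costs only; the effect convention is fixed as above).

`calibrate_conventions` evaluates the full discrete grid (20 distinct
combinations) against the published base-case arm costs (¥1074.00
control, ¥2710.22 fluoride) and ships the minimiser as the package
default: **treatment costs discounted at start of cycle, same-cycle
refill risk, varnish charged on retained teeth and discounted at end of
cycle, no half-cycle correction**. This lands at ¥1068.97 / ¥2713.52
(relative errors 0.47% and 0.12%); no grid point is exact, so the cost
family is reproduced to tolerance rather than to the printed digit, and
the derived incremental cost (¥1644.54 vs ¥1636.22) and ICER (¥161.16 vs
¥160.35) inherit a ~0.5% offset. Honest reverse-engineering of an
under-specified convention beats silently asserting one; the calibration
report (full error table) is available from the function and attached to
the exception on failure.

The varnish charge is ¥8 per tooth per annual cycle. Only a charge of
roughly ¥8 × 23 per year is consistent with the published incremental
cost; the clinical "once every 3 months" application frequency is treated
as descriptive, absorbed into the annual charge and the risk ratio's
effectiveness.

## Incremental analysis

Deltas are fluoride minus control on unrounded totals; the ICER is
`Δcost/Δeffect`, undefined at zero incremental effect (the result then
carries the net monetary benefit `NMB = WTP*Δeffect - Δcost` and an
explicit non-comparability flag). Quadrant labels follow the sign pattern
(dominant: more effective and cheaper). Note that re-dividing the
published *rounded* incremental entries (1636.22/10.20) gives 160.41, not
the published 160.35; comparisons use unrounded pipeline values.

## One-way sensitivity, tornado and thresholds

`one_way` re-runs both arms with a single parameter at a bound (WTP held
at ¥214 throughout — it is a policy threshold, not an uncertain input);
`c_fill` bounds apply to initial fillings and refills alike. The tornado
orders all 13 parameters by ICER range width; the recomputed ordering
reproduces the published one exactly (risk ratio, onset probability,
varnish price on top). Threshold analysis bisects for `ICER = WTP`
(default tolerance ¥0.01), since the ICER is a ratio of Markov-summed
series with no convenient inverse; it finds the risk-ratio crossing at
0.510 (published: 0.512) and the onset-probability crossing at 0.0056
(published as "below 0.006", consistent at the printed precision). One
published range end is not reproduced within 1%: the endodontic-share row
prints 98.58–176.59 while the model gives 101.52–176.85 under the
calibrated conventions; all other rows agree to ~1%.

## Probabilistic sensitivity analysis

Each of 1000 iterations draws one parameter vector shared by both
strategies: the six probabilities from beta(α, β) counts, the risk ratio
from a beta matched by moments to mean 0.396 and SD 0.0396 (10% of the
base value — the source table's literal "0.396/0.097" cells are not
usable as α/β), and all five costs from gamma with SD equal to the mean
(shape 1). Draws violating `p_fill + p_ext ≤ 1` are rejected and redrawn
(probability is negligible under the base specs). The CEAC reports the
fraction of iterations with positive NMB over a 0–800 CNY grid (step 10);
summary intervals are normal-approximation 95% CIs of iteration means.
Freezing the varnish price (`distributions: {c_varnish: {kind: fixed}}`)
is supported since its exponential spread dominates the incremental-cost
uncertainty. The dominant-quadrant fraction is the statistic most
sensitive to the risk-ratio specification choice: across seeds it centres
near 23% against a published 24.6%.

## Microsimulation and synthetic cohort

`simulate_teeth` samples individual trajectories with the *same* event
tree, costs and conventions as the cohort engine, so microsimulated means
are unbiased estimates of the cohort totals (checked at 3 SE with 50,000
teeth). A deliberately independent brute-force oracle — exhaustive
enumeration of all per-tooth event paths over 3 cycles in the test suite
— checks both implementations against exact probability sums to 1e-12,
so the engine/microsimulation agreement is not a self-comparison. A fixed
number of uniforms is consumed per cycle, making runs with different risk
ratios share randomness draw-for-draw (at rr = 1 the fluoride arm
reproduces control trajectories exactly).

`to_exam_dataset` down-samples trajectories to exams every `n` years,
keeping only observed states — the information loss of real longitudinal
follow-up. `estimate_probs` recovers annual probabilities from such
panels: transition proportions per interval, Wilson 95% CIs (stable near
zero), then annualization. For intact→caries the at-risk state has a
single exit, so annualization is exact at any interval; caries→filling
and caries→extraction compete within an interval, so their annualized
estimates carry a small competing-risk bias for `n > 1` (about 5%
relative at `n = 2` with base-case rates) — recovery tests therefore pin
the onset estimate at all intervals and the treatment estimates on annual
panels. Only the three cohort-derived probabilities are estimation
targets; the endodontic, crown and failure probabilities came from
literature and are not part of recovery.

Generator defaults (1,000 subjects × 23 teeth, 2-year exams) are
synthetic stand-ins of a plausible community cohort, not a description of
any actual study: no dropout, no within-mouth clustering, no covariates.
Passing recovery tests validates the estimation pipeline under the
model's own assumptions, not real-world epidemiology.

## Numerical choices and problem sizes

Occupancy conservation is enforced at 1e-12 per cycle; engine-vs-oracle
agreement at 1e-9 (effects) and 1e-12 (3-cycle enumeration); bisection
stops at ¥0.01 on the ICER or a 1e-6 bracket. The test suite uses 200–
1,000 random parameter sets for structural properties, 20,000–50,000
teeth for stochastic-oracle checks, and 100 replicate synthetic cohorts
of 200 subjects for CI-coverage checks; the PSA default is the published
1,000 iterations. Full suite and analysis scripts run in well under a
minute each on a single core.

## Known limitations

- The cost-accrual convention is calibrated, not documented; other
  convention sets within ~3% of the published costs exist, and all
  cost-side results carry the residual ~0.5% offset.
- PSA fractions depend on the unresolved risk-ratio distribution choice;
  alternatives (e.g. a wider beta) shift the dominant fraction by a few
  points while leaving the cost-effective fraction nearly unchanged.
- The estimator's competing-risk bias for treatment probabilities at
  multi-year intervals is documented, not corrected (a multi-state
  likelihood would remove it but is beyond the package's scope).
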