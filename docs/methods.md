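# Methods

## Model

`tccmodel` implements a Markov cohort model of toileting and containment
care (T&CC) for older adults with urinary incontinence in long-term care.
The model compares two care strategies — conventional containment-oriented
care and person-centred care supported by a sensor-based digital bladder
diary (DHT) — on discounted quality-adjusted life years (QALYs), discounted
costs, care hours and absorbent-product waste.

The alive state is the pair *(need group, care stage)*:

* **Need groups G1–G6** order the population by care dependency (cognitive
  ability to express toileting needs, physical ability to toilet). The
  residential case study covers the care-dependent groups G2–G6; group
  membership can only deteriorate.
* **Care stages CS1–CS3** grade toileting success from mainly successful
  toileting (CS1) to mainly containment (CS3). Operationally a resident's
  care stage is classified from the total 24-hour absorbency of the products
  they use (Rothwell units, ISO 11948-1): for average-sized residents CS1
  below 3800, CS2 between 3800 and 5700 inclusive, CS3 above 5700 (large
  residents: 4500/6750). The band endpoints are assigned to CS2 so the three
  stages partition the line exhaustively.
* A single absorbing **dead** state completes the chain: 5 × 3 + 1 = 16
  states for the case study.

**Skin health (SHL1–SHL5)** is deliberately *not* part of the Markov state.
Residents are assigned a skin-health level each cycle conditional on their
care stage and strategy, so skin health is a memoryless per-cycle mixture:
it contributes utility decrements and treatment costs but never influences
dynamics. This collapses what would be an 80-state chain to 16 states with
identical outcomes, because nothing in the model conditions on the previous
cycle's skin level.

Cycles are 2 months (Δt = 1/6 year). The cohort starts at age 86 and is
followed to extinction (survival < 10⁻⁶, capped at 240 cycles; the case
study extinguishes after ~158 cycles, and results are insensitive to the
cap at four decimals). A 5% annual discount rate applies to both costs and
effects, per Canadian guidelines; price year is CAD 2020.

### Within-cycle structure

Each cycle composes three events, isolated in `build_cycle_matrix`:

1. **Death** with a group- and age-band-specific probability (bands 65–74,
   75–84, 85–94, 95+; group classes G1, G4, and G2/G3/G5/G6 share rows).
   Cohort age is a scalar advanced by Δt per cycle, so the mortality band
   switches mid-run (at cycle 54 for start age 86).
2. **Group transition** among survivors (upper-triangular: deterioration
   only).
3. **Care-stage update.** Residents who keep their group follow the
   strategy-specific care-stage transition matrix estimated in the trial.
   For residents who change group the update rule is configurable
   (`settings.group_change_cs_rule`):
   * `"trial"` (default): movers follow the same care-stage matrix as
     stayers.
   * `"shift"`: movers keep their stage with probability 0.10 and worsen
     one stage with probability 0.90, CS3 absorbing.

   The `"shift"` rule is the verbally documented assumption for this model
   family, but applied literally it cannot reproduce the published two-year
   cohort distribution: it yields 21% of DHT-arm survivors in CS3 where the
   published figure is 15% (conventional arm: 42% vs 40%). The `"trial"`
   rule reproduces both arms to within a percentage point (DHT
   21.0/64.8/14.2 vs published 21/64/15; conventional 11.6/49.0/39.4 vs
   12/49/40), so it is the default; the alternative stays one switch away
   and both are exercised by the microsimulation oracle tests.

Transition rows are printed rounded in the sources (one conventional
care-stage row sums to 1.01, two skin rows to 1.001 and 0.995); the loader
renormalizes any row whose sum is within 0.02 of one and refuses rows
further out. Utility decrements are stored as non-negative magnitudes and
subtracted during accumulation.

The initial joint distribution is the product of the group and care-stage
margins (the same initial care-stage split is assumed for every group, as
in the source data). Initial distribution: groups (0.21, 0.46, 0.19, 0.09,
0.05) for G2–G6, care stages (0.16, 0.47, 0.37).

### Outcome accumulation

Life years, QALYs and costs use a **half-cycle (trapezoid) correction**:
each cycle contributes Δt times the average of the discounted start- and
end-of-cycle occupancies. This convention reproduces the expected 2.34
undiscounted life years implied by the mortality table (end-of-cycle
counting gives ≈2.25, start-of-cycle ≈2.42). Discounting is
(1 + r)^(−cycle·Δt) at the cycle boundaries. The dead state contributes
zero utility and zero cost.

QALYs decompose additively, and the decomposition is asserted at 10⁻⁹ on
every run:

* **care-stage component** — group baseline utility minus the care-stage
  decrement;
* **skin-health loss** — expected skin-level decrement under the per-cycle
  SHL mixture for the occupied care stage;
* **care-consequence loss** — adverse-event rate (fracture, UTI,
  constipation, pressure-ulcer categories I–IV; fractures impossible for
  the immobile groups G5–G6, category-I ulcers carry no decrement) times
  the event decrement. Each event is costed as one cycle of its decrement —
  the simplest reading of a "temporary" disutility, and the one that
  matches the published care-consequence component magnitude (−0.030
  conventional) to within rounding.

The care-stage component includes the group baseline stream; defined this
way the three components sum to the published totals. Per-state utility is
floored at zero in `cycle_utility`; the case-study inputs never reach the
floor, and component accumulation is linear (the floor would bind only
under extreme synthetic inputs).

Care hours and disposal kilograms are physical lifetime totals: accumulated
undiscounted, bucketed by group.

### Costs

Costs per person-cycle follow the bottom-up resource-use recipe: task
frequency per day × days per cycle × minutes per task × staff per task ×
blended wage per minute (labour; the blended wage mixes formal and informal
rates by the informal-care share, 0 for the residential case study); daily
product counts × price (absorbent products); hygiene applied at every
product change; dry product weight × disposal tariff (an acknowledged
underestimate of true used-product waste); event rates × cost per event; a
severe-dermatitis (SHL5) treatment episode — one extra staff-minute plus a
unit cost at every product change for 7 days, triggered each cycle with the
care-stage's SHL5 probability; and a per-person-year technology price in
the DHT arm only.

**The bundled economics file is synthetic.** Task minutes and staffing are
transcribed inputs, but unit costs, task frequencies and product profiles
come from sources that are not bundled with the package, so `data/economics_synthetic.yaml` carries plausible placeholder
values flagged `placeholder: true` (the flag propagates to run manifests
and CLI warnings). Cost results obtained with it characterise the model
mechanics — additivity, linearity in unit costs, discount behaviour — not
the published Canadian totals, which the effect side never needs.

## Sensitivity analysis

**One-way (tornado).** Every scalar parameter is set to the bounds of its
95% interval (reported CI where available — e.g. the mortality table —
otherwise mean ± 1.96·SE with SE = 20% of the mean), holding all else at
base, and the deterministic comparison is re-run. Stochastic rows carry no
printed interval and vary only in the PSA. Fixed by design: cycle length,
horizon, discount rate, the CS1 and SHL1 decrements (structural zeros) and
the G2–G3 staff counts. With the bundled inputs the CS3 utility decrement
produces the widest incremental-QALY range, (0.0088, 0.0197) around the
base 0.0143; the published tornado shows a wider (0.006, 0.024) envelope
for this parameter, implying decrement CIs wider than the 20% default that
the main text does not report.

**Probabilistic.** All non-fixed parameters are drawn simultaneously
(default 5,000 iterations, fixed seed, one child seed per iteration so any
draw can be regenerated in isolation):

* **Beta**, moment-matched from (mean, SE = 20% of mean), for probabilities
  and [0,1] decrements (event rates, event decrements);
* **Gamma**, moment-matched (shape 25 at the 20% default), for unit costs
  and resource use;
* **Normal** for age, mortality (SE from the reported CI) and group/CS/SHL
  utility values and decrements, truncated to the admissible range by
  resampling (the sources do not say how out-of-range draws were handled;
  truncation preserves support at a small cost in mean shift);
* **Dirichlet** for every stochastic row (initial distributions, group,
  care-stage and skin rows), with total concentration scaled so the
  largest-mean component has SE = 20% of its mean, floored at 1 where the
  row is too concentrated to admit that spread; structural zeros keep zero
  mass, and degenerate rows stay fixed.

Start age uses SE = 2 years: the generic 20%-of-mean default is meaningless
for an age (it would put mass below the model's 65-year floor), so a modest
prior spread truncated to ≥65 is the package's own choice.

Mortality, group transitions, initial distributions and utilities are
shared inputs: drawn once per iteration and applied to both arms.
Arm-specific tables (care-stage and skin transitions, event rates,
arm-specific resource use) are drawn independently per arm.

The PSA mean incremental QALY gain (≈0.0147 at n = 5,000) sits slightly
above the deterministic 0.0143, the same upward skew the published analysis
shows (0.016 vs 0.015): the QALY difference is a convex function of the
jointly varied transition rows. The cost-effectiveness acceptability curve
reports, for each willingness-to-pay λ, the fraction of iterations with
non-negative net monetary benefit λ·ΔE − ΔC; CE-plane quadrant shares use
ΔC ≤ 0 as the cost-saving half so that CEAC(0) equals the cost-saving
share exactly.

## Synthetic parameter generation

`generate_synthetic_params` produces fully valid random parameter sets for
testing: Dirichlet rows around the case-study means (concentration 50;
uniform on the admissible simplex when no template is given), Beta-perturbed
probabilities and utilities, Gamma-perturbed costs. Structural zeros (group
ordering, impossible fractures, degenerate rows) are preserved, so every
draw passes validation by construction. The generator emulates parameter
uncertainty around the study conditions; it does not emulate resident-level
trial data, so passing tests say nothing about estimating inputs from such
data.

## Verification

The engine's primary correctness check is an independent microsimulation
oracle: 100,000 individuals follow the same verbal rules through
per-person pseudo-random draws, and the cycle-12 state distribution is
compared with the cohort result using a joint multinomial chi-square test
(α = 0.001) — the correctly calibrated version of "each state within
Monte-Carlo error" when 16 states are compared simultaneously. Further
invariants tested on every run: mass conservation at 10⁻⁹, monotone
survival, no flow to lower-indexed groups, QALY-component additivity,
QALY = discounted LY when utilities are 1 and decrements 0, equality of
discounted life years across arms (mortality is strategy-independent),
linearity of losses in decrements and of costs in unit prices, PSA
degeneration to the deterministic result when all SEs are 0, and bitwise
reproducibility of every seeded output.

## Known limitations

* The published "57% alive after 2 years" is not reproducible from the
  printed mortality inputs (any standard application order gives ≈42%);
  the same inputs do reproduce the published 2.34 life years under the
  half-cycle convention, so the survival figure is treated as anomalous.
* Care-stage transitions were measured over 8 weeks but applied per
  2-month (~8.7-week) cycle without rate conversion, following the source.
* Effectiveness is assumed constant over the remaining lifetime, and no
  excess mortality is attached to incontinence severity or skin health.
* The economics fixture is synthetic (above); published cost totals are
  documentation targets only.
* Disposal mass uses dry product weight, underestimating true waste.
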