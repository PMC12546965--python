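# Methods

## Scope and model structure

`pouchcea` implements two discrete-time Markov cohort models comparing
daily prophylaxis with an 8-strain probiotic against no prophylaxis in
patients with an ileal pouch–anal anastomosis for ulcerative colitis:

* **Primary prevention** (2-week cycles, 52 cycles over the 2-year base
  horizon): a pouchitis-naive cohort starts pouchitis-free.  The first
  episode triggers a diagnostic workup ($612.60) and a ciprofloxacin
  course; failures escalate to metronidazole and then to a 4-week dual
  ciprofloxacin/tinidazole course (a two-cycle tunnel).  Responders enter a
  line-specific remission; recurrences (39%/y) are retreated with the
  previously effective antibiotic, and failure of that antibiotic
  escalates to the next line — the only reading under which ~7.3% of the
  unprotected cohort can reach dual antibiotics by 2 years.  Probiotic
  users take the probiotic ($87.20 per 2 weeks) only while pouchitis-free.
  Variants: `base`; `empirical_workup` (workup deferred to the first
  recurrence or first antibiotic failure, a cost-only change — QALYs are
  identical by construction); `extended_biologics` (dual-antibiotic
  response 0.69 instead of the structural 1.0, with nonresponders moving
  to vedolizumab and then an absorbing infliximab remission).
* **Secondary prevention** (4-week cycles, 26 cycles): a relapsing-pouchitis
  cohort starts in remission.  Relapses (14%/y on probiotic, 39%/y
  without) are treated empirically without workup: ciprofloxacin →
  metronidazole → dual antibiotics (response 0.77/0.70/0.69); dual failure
  defines chronic antibiotic-refractory pouchitis (CARP), charged a
  one-time evaluation ($128.40), after which the probiotic stops and
  vedolizumab starts (response 0.52 assessed after induction, loss of
  response 40%/y), with infliximab as an absorbing remission (structural
  100% response, dosing costs continue to the horizon).  Probiotic users
  continue the probiotic ($174 per 4 weeks) through relapses until CARP.

States with forced duration (antibiotic courses, biologic induction,
periodic dosing) are expanded into explicit state chains so every model is
first-order Markov and time-homogeneous.  Only two utilities exist: 0.91/y
while in any remission and 0.46/y during any active episode (antibiotic
courses and vedolizumab induction).

## Conventions

* **Probability conversion.** Annual probabilities become per-cycle
  probabilities by the constant-hazard formula `1-(1-p)^t` with `t` the
  cycle length in years (1/26 or 1/13, so integer years are exact).  This
  reproduces the published 2-year incidences exactly (64%/19% primary,
  62.8%/26.0% secondary; the Discussion's 73% figure for the unprotected
  secondary arm is inconsistent with its own 39%/y input and is not
  force-fitted).
* **Rewards.** State-membership rewards (per-cycle costs; annual utility ×
  cycle length) accrue for the whole cycle at the cycle-start discount
  factor; no half-cycle correction.  One-time costs (workup, antibiotic
  course, CARP evaluation) are charged on the triggering transition at the
  destination cycle's discount factor.
* **Discounting.** The engine supports two bases.  Under the textbook
  `annual` basis the factor for cycle `k` is `1.03^(-k·t)`.  The published
  cumulative totals, however, are only reproducible when the 3% rate is
  applied **per cycle** (`1.03^(-k)`), a decision-software configuration
  quirk we identified by reconciliation: under it the probiotic-arm costs
  come out at $2,244 vs the printed $2,223 (primary) and $3,342 vs $3,370
  (secondary), and the QALY levels land near the printed 0.92–0.94 range,
  whereas the annual basis gives roughly twice the printed accruals.  The
  `cycle` basis is therefore the default throughout the reproduction
  pipeline; incremental ratios, thresholds, and PSA classifications are
  nearly basis-invariant because both arms are discounted identically.
* **Biologic dosing.** Weeks-0/2/6-then-every-8-weeks schedules cannot sit
  exactly on either cycle grid.  On the 4-week grid induction is
  compressed to {cycle 0: 1 dose, cycle 1: 2 doses} with maintenance from
  cycle 3 every 2 cycles; on the 2-week grid doses fall exactly on cycles
  0, 1, 3 and then every 4 cycles.  Infliximab is priced per 300 mg and
  pro-rated linearly to 5 mg/kg × 70 kg (scale 350/300); the body weight
  is adjustable.

## Parameters

All inputs live in a typed registry (`pouchcea.params`) carrying the
base-case value, the triangular Monte Carlo range, a role that implies
validity bounds (probabilities and utilities in [0,1], costs ≥ 0), and a
time-basis suffix in the name to prevent unit errors.  Where the two
published tables print the same quantity with different Monte Carlo ranges
(dual-antibiotic cost, ciprofloxacin/metronidazole responses), each model
scope keeps its own spec.  The infliximab response is stored as the
degenerate range 1.0–1.0 and is therefore never sampled; infliximab
remission is structurally absorbing, so overriding that value has no
effect.  Two printed inconsistencies are resolved in favour of the
base-case tables: the 4-week probiotic cost is stored as $174 (the text
elsewhere says $175), and the no-pouchitis utility as 0.91 (a sensitivity
table lists 0.68).

## Sensitivity analyses

* **One-way (OWSA).** A sweep evaluates the full pipeline on an
  equally-spaced grid (default 199 points), classifies each point at the
  chosen willingness-to-pay, and refines every classification change by
  bisection to 1e-4 of the sweep width.  Sweeps may leave the Monte Carlo
  ranges (the published sweeps go to 0–99% and $1–$10,000) but never the
  role bounds.  For drug costs the net monetary benefit is affine in the
  parameter, so bisection is checked against the exact interpolated root
  in the tests.
* **Probabilistic (PSA).** Each draw samples every non-degenerate
  parameter independently from triangular(min, mode=base, max) in registry
  order from one seeded generator (the order is part of the
  reproducibility contract), resampling the two utilities jointly until
  remission utility ≥ active-episode utility.  Each draw is evaluated by
  the deterministic cohort model (second-order uncertainty), classified at
  the reference willingness-to-pay, and tallied; acceptability curves
  report the fraction of draws with positive net monetary benefit across a
  $0–$500,000 grid.

## Microsimulation oracle and synthetic data

`pouchcea.microsim` simulates individual trajectories from the same
transition matrices and replays the cohort engine's reward code (shared
functions, not a re-implementation), so agreement between the aggregated
trajectories and the cohort trace — checked at 50,000 patients within 4
binomial standard errors on every state × cycle cell — isolates the
transition logic.  An independent hand-written accrual path exists only in
the test suite for double-entry checking of the reward conventions.  Each
patient's stream derives from (master seed, patient index), so estimates
are order-independent.  The same triangular sampler generates synthetic,
bounds-respecting parameter sets for property-based tests.  The generator
emulates parameter uncertainty and trajectory noise of the cohort models
only; it does not emulate real-world features such as adherence,
practice variation, or correlated parameters, so passing tests show
internal consistency, not external validity.

## Reproduction of published values, and known failures

With the conventions above the package reproduces: the 2-year incidences
exactly; the base-case ICERs to 0.4% (primary, $235,140 vs $236,076) and
4.7% (secondary, $145,834 vs $153,011); the probiotic-arm costs to ~1%;
the one-way thresholds to within 1.4 points / $5 (77.4% vs 76%, $41.2 vs
$42, 46.7% vs 48%, $126 vs $121); and the trace landmarks (2.1%/7.6% dual
reach, 0.36%/1.38% infliximab reach) within 1.5 points.

Two published quantities resisted reproduction and are documented rather
than force-fitted:

1. **Primary comparator-arm cost ($299).** The stated pathway (workup at
   the first episode only) yields $243.  The ~$56 gap matches the
   discounted expected cost of charging the evaluation at recurrent
   episodes as well, suggesting the source model did so; we follow the
   stated clinical pathway.
2. **Primary Monte Carlo fractions (22.9% cost-effective at $100k; 94%
   acceptable at $500k).** Under the printed parameter ranges the ICER
   distribution never falls below ~$140k (5th percentile ≈ $187k) — which
   the published one-way analysis itself corroborates, since
   cost-effectiveness requires a probiotic cost below $42 (range floor
   $50) or a first-episode probability above 76% (range ceiling 50%).  No
   interpretation of the Monte Carlo procedure we examined (parameter
   draws over the cohort model; patient-level trials with independent or
   common random streams, with or without parameter draws) reproduces
   both models' printed fractions simultaneously; the secondary model's
   printed pattern (2.9% cost-effective, 12.7% inferior) is closest to
   the parameter-draw interpretation implemented here (≈5%/≈10%).

## Problem sizes

The shipped analyses use the published problem sizes: 52- and 26-cycle
cohorts, 199-point one-way grids with bisection refinement, 1000-draw
PSAs (with a 20,000-draw stability rerun in the test suite), and a
50,000-patient microsimulation for oracle equivalence.

## Limitations

No background mortality, pouch failure, dysplasia, or currency-year
adjustment; exactly two strategies per model; no parameter correlations in
the PSA; biologic dose timing is approximated to the cycle grid as
described.  Five-year scenario ICERs are sensitive to the absorbing
infliximab assumption and drift from the published figures (ours $120,901
vs $149,706 for the secondary model) while the 1-year scenarios agree to
~1–3%.
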