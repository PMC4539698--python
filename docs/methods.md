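# Methods

## Model structure

A deterministic Markov cohort model with states {GOLD II, GOLD III, GOLD IV,
DEAD} and three-month cycles.  The cohort enters at age 65 distributed
(48 %, 44 %, 8 %) over the alive states and is followed until age 100 (140
cycles); the final cycle ends the simulation with no terminal tail value.
Within a cycle the order of operations is:

1. **Event split.** Each alive state's mass splits across
   {no exacerbation, non-severe exacerbation, severe exacerbation} by the
   arm's event table.  Published event rows are rounded to two decimals and
   do not always sum to one; the no-exacerbation probability is always
   recomputed as the complement of the printed non-severe and severe
   probabilities, which are the cost- and mortality-bearing categories.
2. **Accrual.** Costs (state–event direct cost plus drug cost while on
   treatment), utilities (annual weight × 0.25) and life-time accrue for
   the full cycle, multiplied by the cycle's discount factor
   (1+r)^−(k−1)·0.25 with the first cycle undiscounted.  Patients dying in
   the cycle accrue the full cycle, including the hospitalisation cost of a
   fatal severe exacerbation.  No half-cycle correction is applied: the
   source model class does not use one, and the life-year calibration
   absorbs level effects.  Event counts and person-years accumulate
   undiscounted.
3. **Death.** The state- and age-specific per-cycle death probability
   applies, with the per-event severe-exacerbation excess added for the
   severe fraction (total capped at 1).  The excess applies only in the
   event cycle; no persistent post-event mortality is modelled.
4. **Transition.** Survivors move by a 3×3 matrix conditional on survival
   (applied without renormalisation, since death is carried separately).

**Phases.** Cycle 1 uses the first-cycle matrices (capturing the initial
30-day bronchodilator response); cycles 2–16 the subsequent-treatment
matrices; from cycle 17 (after the 4-year treatment period) the active arms
revert to usual-care transition *and* event probabilities, reflecting the
lack of persistence of LAMA effect after discontinuation.  The event-risk
reversion is an interpretation — the source material states the reversion
explicitly only for transition probabilities — and is exposed as the
configuration switch `options.revert_event_risks_off_treatment`; keeping
arm-specific risks for life materially changes the lifetime head-to-head
comparison (see Limitations).  Drug cost (price/day × 91.3125 days/cycle)
is paid by everyone alive in cycles 1–16 of an active arm.

**Treatment effects.** Tiotropium vs usual care acts through both slower
transition to worse states and lower non-severe exacerbation risk.
Glycopyrronium shares tiotropium's transition matrices (equivalent effect
on lung function) and differs only in exacerbation risks; its base-case
event table is the published one, and when the severe relative risk
(GLY/TIO = 1.43, 95 % CI 1.05–1.97) is varied, the table is re-derived from
the tiotropium baseline as sev' = min(1, sev × RR), nonsev' = nonsev × RR_ns
(RR_ns = 1 in the base case), no-exac as complement.

## Mortality synthesis and calibration

Background mortality is a Gompertz–Makeham law, annual hazard
h(x) = a + b·e^(c·x), least-squares fitted (log-hazard scale, ages 50–100)
to Swedish-type total-population one-year death probabilities circa 2012:
a = 1.6186e−3, b = 1.5812e−6, c = 0.12936.  It is a parametric stand-in for
the national life table, chosen to keep the package free of external data;
its residual level error is absorbed by the calibration scales.  An
age-constant 3 % of deaths (the approximate Swedish share with ICD-10 J44
as underlying cause) is removed so disease-specific excess is not counted
twice.

Excess mortality has two components with literature-class default point
estimates at the reference age 65:

* **GOLD-state excess**: relative risks (1.3, 2.0, 3.3) for states II–IV
  applied on the *hazard* scale, annual probability
  1 − (1 − q0)^(1 + s·(RR(x) − 1)).  Probability-scale multiplication,
  the naive alternative, exceeds certainty for GOLD IV beyond age ~99 under
  any realistic background; the hazard-power form is first-order identical
  and valid at all ages.  The excess (RR − 1) decays by a factor 0.85 per
  decade of age (relative risks shrink as absolute risks grow), evaluated
  at whole-decade knots with linear interpolation.
* **Severe-exacerbation excess**: an additive per-event death probability,
  0.10 per event at 65, growing by a factor 1.3 per decade (same knot
  scheme), capped at 1.

The two global scales — s on (RR − 1) and the multiplier on the per-event
excess — are the free parameters.  They are calibrated by nested
bracketing/Brent root-finding so the usual-care and glycopyrronium arms
reproduce the published discounted life expectancies (10.18 and 9.93 years
at 3 %): the inner solve pins the severe-exacerbation scale on the
glycopyrronium anchor for each candidate state scale, the outer solve pins
the state scale on the usual-care arm.  Convergence is verified to 1e−3
years on both anchors (about a hundred cohort runs, each a few
milliseconds); the procedure is deterministic and idempotent, and the
result is written to a JSON sidecar with its provenance.  The tiotropium
arm is deliberately excluded from the fit: its predicted 10.23 discounted
life years against the published 10.26 is an out-of-sample check of the
whole mortality structure.  On the packaged base case the calibrated scales
are ≈ 0.90 (state) and ≈ 1.28 (per-event), i.e. a calibrated per-event
severe-exacerbation case fatality of ≈ 13 % at 65.

## Economics

ICERs are computed on unrounded accumulators (published rounded deltas are
internally inconsistent with the published ratios).  Dominance is labelled
when the sign pattern leaves no trade-off (cheaper and at least as
effective, or the mirror image); equal costs and effects are labelled
equivalent; both trade-off quadrants report the ratio.

## Sensitivity analyses

**One-way scenarios** are declarative patches on the configuration, one
full model run per scenario and comparison.  Calibrated scales are reused
unless a scenario explicitly changes them (the ±20 % severe-exacerbation
excess rows scale the calibrated value).  Two rows are approximations with
no published inputs to pin them: sex-specific rows are encoded as scalar
background-hazard adjustments (males ×1.25, females ×0.80) without
recalibration, and the start-age rows reuse the age-65 calibration because
no anchors exist for those populations.

**PSA** (default 10,000 iterations): the severe-exacerbation relative risk
is drawn lognormally with median at the point estimate and
σ = (ln hi − ln lo)/(2·1.959964) = 0.1606 from its 95 % CI; every cost and
utility cell is drawn independently and uniformly within ±20 % of its point
estimate (utilities truncated at 1; no correlation structure is imposed, so
drawn tables can violate the deterministic orderings — that is the stated
design).  The glycopyrronium event table is re-derived from each drawn
relative risk.  Draws yielding an invalid probability table are redrawn
wholesale and counted (with the published inputs this essentially never
triggers).  The calibrated mortality schedule is held fixed across
iterations.  Iteration i uses an independent generator keyed (seed, i), so
runs are bit-reproducible and any single iteration can be reconstructed
without the rest; the whole PSA propagates all iterations through the
cohort model as one vectorised batch, whose equivalence to the scalar
engine is asserted by tests.  The treatment-effect CI for the
tiotropium-vs-usual-care comparison is not published; no default is
fabricated, so the usual-care-side PSA varies costs and utilities only
unless the user supplies that distribution.

The mean PSA deltas centre on the deterministic base case when only the
symmetric cost/utility distributions are active; with the skewed lognormal
relative risk the mean deltas sit above the base case, which is expected
and not corrected.

## Synthetic inputs and what tests show

The packaged configuration carries the published tables verbatim and is the
single source for all reproduction runs.  The random parameter generator
produces validator-passing inputs (diagonally dominant transition matrices,
ordered cost/utility tables, jittered Gompertz–Makeham laws) plus
degenerate corners (zero mortality with identity transitions; point-mass
initial distributions) used as engine fixed points.  These synthetic inputs
emulate the *structure* of the study inputs, not Swedish reality: passing
property tests demonstrates conservation laws, monotonicities and oracle
equivalence of the implementation, no more.  Reproduction of the published
economics is checked only through the packaged configuration.

## Numerical choices

Rounded published transition rows are accepted within 0.02 of unit sum and
renormalised exactly; event rows are completed by complement.  Occupancy
mass is conserved to 1e−12 per cycle and asserted.  Probability
conversions use the constant-hazard map 1 − (1 − p)^L.  Root-finding uses
bracket doubling plus Brent with 1e−7–1e−8 bracket tolerance, verified at
1e−3 years on the anchors.  An 8-cycle explicit-enumeration oracle agrees
with the engine to 1e−9 on every accumulator.

## Known limitations

* The GOLD-state excess point estimates behind the published model are not
  printed; calibration pins their overall level (and the severe-exacerbation
  split) but not the II-vs-IV spread.  With our literature-class defaults
  the usual-care-side incremental life years come out 0.049 vs the
  published 0.08, so tiotropium-vs-usual-care ICERs sit a uniform ~35 %
  above the published values while every glycopyrronium-side contrast and
  all per-arm totals track closely.
* The published 4-year annualised severe-exacerbation validation rate
  (0.24/patient-year, usual care) is arithmetically unreachable from the
  published three-month event probabilities, which bound the rate near
  0.17 even at the GOLD-IV-heavy stationary distribution; the model reports
  its true value (≈ 0.16).
* The published probabilistic result (90 % acceptability at SEK 600,000 per
  QALY for the LAMA head-to-head) implies more parameter uncertainty than
  the published distribution list generates: with the printed lognormal CI
  the break-even relative risk is ≈ 1.01 and the model's acceptability is
  ≈ 98–99 %.
* No microsimulation mode, no exacerbation history dependence, no
  indirect costs, no efficiency frontier beyond the two pairwise
  comparisons, and no figure rendering (data series are exported as CSV).
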