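# Methods

## Model structure

The package implements a two-phase cost-effectiveness model of biologic
therapy in moderate-to-severe Crohn's disease.

**Induction phase (decision tree).**  Everyone enters moderate-to-severe
(CDAI ≥ 220) and receives the first induction dose.  At the assessment
visit the cohort splits by the remission rate α, the response rate β and
the fraction γ of responders who remain moderate-to-severe: remission α,
mild β − (α + β·γ), moderate-to-severe β·γ, non-response 1 − β.  The split
is feasible only when β ≥ α + β·γ; infeasible parameter combinations raise
an explicit error rather than clipping.  First-dose non-responders receive
a second dose and are assessed with the same split applied to the
second-dose rates; the second-dose rates are interpreted as *conditional on
first-dose non-response* (tree semantics — the sources do not state whether
they were measured on all comers).  Remaining non-responders move to
non-biologic standard of care (SoC) in the moderate-to-severe state.  A
one-off induction surgery probability (default 0.02) is then drawn
proportionally from all branches.

Induction-phase accrual: every patient accrues health-state costs, indirect
costs, adverse events and QALYs at the moderate-to-severe rates — everyone
starts there and the timing of within-induction improvement is not
modelled.  First-dose responders accrue over the treatment-specific
induction span (8/4/10 weeks for ustekinumab/adalimumab/vedolizumab);
everyone routed through the second dose accrues to the second assessment
(week 16/12/14).  Drug and administration costs follow the dosing schedule;
all induction injections and infusions are in-hospital (IV €257, SC €124
per occasion, each occasion counted once regardless of dose), while
maintenance subcutaneous injections are self-administered at no cost.
The weight-based ustekinumab IV induction dose (260/390/520 mg by weight
band) is costed as the band-weighted expected dose at a pro-rata per-mg
price derived from the 90 mg pack (the IV vial price is unpublished); this
is an expected-cost weighting over the printed weight-band fractions, not a
microsimulation of weight.

**Maintenance phase (Markov cohort).**  The expanded state space is CDAI
state × treatment status (standard-dose biologic, escalated-dose biologic,
SoC) plus one surgery cell per status of origin and an absorbing death
state — 13 states.  Status must be tracked because discontinuation and
dose-escalation probabilities are dose-level specific.  Within each 2-week
cycle, events apply in a fixed documented order:

1. background mortality by current cohort age, from every alive state
   (first, so dead mass never transitions);
2. surgery exit after exactly one cycle in the surgery state, to the
   post-surgery CDAI distribution, within the originating status track;
3. surgery intake from the CDAI states at the per-cycle rate converted
   from the annual rate by `1 − (1 − p)^(w/52)`;
4. discontinuation to SoC, applied only to moderate-to-severe occupants on
   biologic (lack of efficacy is equated with that state), at the
   status-specific per-cycle probability, while on treatment;
5. dose escalation (standard → escalated) at the treatment's per-cycle
   probability, while on treatment and when the escalation flag is on;
   escalated patients never de-escalate;
6. CDAI transition by the status-appropriate 3×3 matrix.

The event order is a modelling choice the sources leave open; a fixed order
is required for reproducibility, and mortality-first avoids transitioning
dead mass.  Mass conservation is asserted in-engine each cycle at 1e-9.

After the treatment duration (default 2 years, counted from model entry),
drug exposure, discontinuation and escalation stop, and the biologic
tracks' transition matrix blends linearly into the SoC matrix over the
treatment-specific convergence period (`convergence_cycles`), modelling
gradual post-treatment efficacy decline.  Patients remain in their track
labels; economics treats them as SoC recipients from the switch cycle on.

**Calibration.**  Maintenance efficacy evidence enters as a target
(remission, mild) distribution at the end of the maintenance period.  The
per-cycle biologic matrix is found by minimising the sum of squared
deviations of the propagated remission and mild fractions from the target,
with rows parameterised on the simplex (softmax) and a bounded local
optimiser (L-BFGS-B) restarted from 10 seeded starting points plus any
user-supplied start.  Ties are broken by (objective rounded at 1e-12, then
lowest entry entropy) for reproducibility.  Convergence is declared at an
objective ≤ 1e-8; otherwise the best constrained local minimum is returned
with `converged=False` and an iteration record — never silently.  With two
targets and six free parameters the problem is under-determined; the result
object states the non-uniqueness.  The generic operation supports fixed
entries and an optional monotone-stay constraint (stay probability ≥ each
single leaving probability, as a soft penalty), both off by default.  The
*pipeline* calibrates with the monotone-stay constraint enabled: without
it, the optimiser frequently returns "churning" matrices (e.g.
remission→remission ≈ 0.04) that meet the two-point objective yet imply
clinically absurd fortnightly state swings and distort every intermediate
cycle — precisely the start-value sensitivity for which the original
spreadsheet-Solver approach was criticised.  Diagonal dominance is the
mildest structure that rules these out.

**Economics.**  Costs are societal: drug acquisition (pro-rated over the
dosing interval, e.g. a €3546 dose every 12 weeks contributes €591 per
2-week cycle), administration occasions (lumped at dose cycles, IV
maintenance only), health-state resource use and indirect productivity
costs (per-state 2-week values), adverse events (per-cycle event rates on
the treated population × unit costs), SoC drug cost (for SoC occupants,
post-treatment patients, and — at the concomitant fraction, default 50 % —
patients on biologic), and surgical complication costs (surgery intake ×
complication probability).  QALYs weight start-of-cycle occupancy by state
utility; adverse events subtract one cycle of their disutility per event.
Discounting uses `(1+r)^(−t)` with `t = cycle_index × 14/365.25` years from
model entry; the induction phase enters at time zero undiscounted (≤ 16
weeks; the forgone factor is < 1 %).  No half-cycle correction by default,
replicating the spreadsheet-style accrual of this model family; a
`half_cycle_correction` flag averages adjacent occupancies instead.  Two
deliberate unit conventions coexist, as they do in the source family:
probabilities and horizons count 26 cycles per year (52-week year), while
calendar time for discounting uses 14/365.25-year cycles.

The incremental analysis classifies the sign pattern (intervention
dominates / comparator dominates / ICER reported / degenerate when
|ΔQALY| < 1e-12) and refuses to compare results produced under different
discount or horizon settings.  The `include_ae_effects` flag removes the
adverse-event *utility* decrements only; adverse-event costs remain, since
the scenario is about the effect of adverse events on health.

## Parameters

All monetary values are 2016 EUR (SEK converted at 0.1057 at authoring
time).  Key defaults: cycle length 2 weeks; horizon 60 years; treatment
duration 2 years; discount rates 3 %/year for costs and effects; induction
surgery 2 % once; surgery 7 %/year thereafter; utilities 0.80/0.68/0.55 for
remission/mild/moderate-severe with surgery at the moderate-to-severe
value and death 0; reference willingness to pay €63,000 per QALY.
Treatment-specific inputs (dosing schedules, induction efficacy per
population, per-cycle discontinuation and escalation probabilities) ship in
the two packaged YAML bundles.  Escalated-dose regimens are unpublished;
escalation is modelled as an interval-shortening cost multiplier (1.5 for
ustekinumab q12w→q8w, 2.0 for adalimumab and vedolizumab, synthetic).

## Synthetic stand-ins

Inputs the model needs but no public source prints are generated by
`cdcea.synthetic` and always flagged `[synthetic]`:

- **SoC transition matrix** — biased toward deterioration (per-cycle
  remission→mild 0.05, mild→moderate-severe 0.08, moderate-severe→mild
  0.03, with small recovery entries 0.02/0.01 so the chain is not
  absorbing);
- **post-surgery distribution** — (0.50, 0.30, 0.20) over
  remission/mild/moderate-severe;
- **mortality** — Gompertz-shaped all-cause annual probability
  `3×10⁻⁵·e^(0.085·age)` (≈ doubling every 8 years), converted per cycle,
  ages 30–110; explicitly *not* an official national life table and with no
  disease-specific excess mortality;
- **maintenance targets** — end-of-maintenance (remission, mild) fractions
  per treatment, ordered so the intervention's remission target is at least
  the comparator's, as the relative-efficacy evidence implies
  qualitatively;
- **surgical complication probability** — 0.15 (range 0.05–0.30);
- **adverse-event unit costs, SoC drug cost, convergence periods,
  CDAI-70 efficacy sets, alternative utility sets** — plausible values
  packaged in the baseline YAML and listed under `provenance_synthetic`.

The generator is seeded and deterministic; with jitter 0 it returns the
defaults verbatim.  What passing tests show, therefore, is that the
*machinery* is correct — splits, calibration, cohort dynamics, accrual,
uncertainty propagation — under realistic-shaped inputs.  They do not show
that the packaged base case reproduces any published total: those depend on
the unpublished calibrated matrices, targets, mortality and SoC inputs.
Consistent with that, the packaged defaults reproduce the *direction* of
the published comparison (a QALY gain for the intervention in both
populations) but not its magnitudes or cost signs.

The module also provides an individual-level microsimulation that applies
the identical event order by categorical draws per patient, sharing no
transition code with the cohort engine.  Agreement between the two (cohort
occupancy within 3 Monte-Carlo standard errors of the 100,000-patient
microsimulation mean in ≥ 99 % of cycle×state cells on random scenarios) is
the keystone engine-correctness check.

## Probabilistic sensitivity analysis

Distribution families follow standard health-economic practice (the
sources state none): beta by method of moments for probabilities,
utilities and disutility magnitudes; gamma for costs; lognormal
multiplicative noise on odds for efficacy; Dirichlet for transition-matrix
rows (effective sample size 200 by default, structural zeros preserved).
The default uncertainty scale is a standard error of 10 % of the mean.
Biologic matrices are calibrated once from the base inputs and perturbed
per iteration rather than re-calibrated — re-running an under-determined
calibration inside the PSA would conflate optimiser path noise with
parameter uncertainty, and the Dirichlet perturbation expresses matrix
uncertainty directly.  Draws violating any input invariant (including
induction-split feasibility) are redrawn with a bounded retry budget.
Iterations use deterministic substreams spawned from the seed, so the PSA
is exactly reproducible from (seed, iterations, spec).  CEACs report, per
willingness-to-pay value, the fraction of iterations with strictly positive
net monetary benefit; an NMB of exactly zero counts as not cost-effective.
The WTP grid runs 0–200,000 in steps of 1,000, containing the €63,000
reference exactly.

## Numerical and degenerate-input choices

- Row-stochasticity tolerance 1e-9 throughout; in-engine mass conservation
  asserted at 1e-9 and renormalised to absorb accumulated float rounding.
- β = 1 (universal response): the second-dose branch carries zero mass and
  zero cost.  β = 0: the whole cohort moves to SoC; the biologic track is
  empty and calibration is skipped (any valid matrix is equivalent).
- Printed weight-band fractions that sum to within 0.5 % of 1 (the
  TNF-failure bands print as 100.1 %) are renormalised at load; larger
  discrepancies are validation errors.
- Validation is total: a corrupted document is rejected with a message per
  violated field, all violations listed, paths named.
- The mortality table must cover every age reached before the horizon;
  exhaustion is an error, not an extrapolation.

## Problem sizes

The packaged base case runs 1,560 two-week cycles (60 years) per arm; the
default PSA runs 1,000 iterations per population; the engine cross-check
simulates 100,000 patients for 50 cycles; property sweeps run 100 random
end-to-end scenarios at 3–8-year horizons.  These sizes are the model's
study conditions, chosen to match the analysis design and to keep
Monte-Carlo error far below the effects examined.

## Known limitations

- No treatment sequencing or re-treatment; discontinued and post-treatment
  patients stay on SoC until death (a stated limitation of this model
  family).
- No increased relapse risk after biologic withdrawal beyond the matrix
  convergence, and surgery history does not raise future surgery risk.
- Cohort-level weight handling only (expected dose cost over weight bands).
- The calibration's two-target objective cannot identify a unique matrix;
  results should be read conditional on the monotone-stay structure.
- Synthetic stand-ins are shaped to be realistic, not estimated from data;
  absolute cost and QALY levels inherit that arbitrariness.
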