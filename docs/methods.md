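# Methods

## Model

`markovcea` implements a discrete-time Markov cohort model of dependency
in community-dwelling older adults. The state space is ordered
(mild, moderate, severe, total, death): four levels of dependency in
personal and instrumental activities of daily living plus an absorbing
death state. A unit cohort mass `s_0` (by default concentrated in
severe dependency, the state that represents bathing disability) is
propagated through annual cycles,

    s_t = s_{t-1} P_t ,   t = 1..T,

where `P_t` is the row-stochastic annual transition matrix for cycle
`t`. The default horizon is T = 8 years, matching the remaining life
expectancy of the modelled cohort (mean age 82).

Each state carries two rewards: a quality-of-life utility `u` in
[0, 1] and an annual societal cost `c` in euro (health care, home
care, informal care and accommodation). Cycle-t accruals attach to the
post-transition distribution — a person who recovers during a year is
credited the destination state's utility and cost for that whole year;
no half-cycle correction is applied. This convention is what the
shipped default inputs were calibrated under and is the one that
reproduces their published QALY totals.

    QALY_t = s_t · u,   Cost_t = s_t · c (+ intervention cost in cycle 1).

### Discounting

Both QALYs and costs are discounted at a single annual rate r (default
0.03). Two exponent conventions are selectable:

- `from-first-cycle` (default): factor `(1+r)^-t` for cycle t, i.e.
  even the first year's rewards are discounted once;
- `after-first-cycle`: factor `(1+r)^-(t-1)`, taking the first year at
  face value.

With the shipped inputs the first convention yields the published
8-year control total of 2.211 QALYs; the second yields 2.277. The
intervention's one-off per-person cost is charged in cycle 1 and
discounted with that cycle's factor, symmetric with all other cycle-1
flows (switching it to undiscounted moves totals by less than 4 €).

### Intervention effect

The intervention (a reablement programme promoting independent
bathing) is modelled as a relative increase of the severe → moderate
recovery probability during the first annual cycle only:
`p' = m * p` with multiplier m = 1.4 (1.2 in sensitivity analysis).
The added mass is taken from a donor transition in the same row — by
default the severe → severe diagonal, which leaves the decline and
mortality probabilities of the severe state untouched. The exact
product 1.4 × 0.12 = 0.168 is used rather than a rounded 17%;
rounding changes the incremental QALYs from 0.052 to 0.055.
Modification errors (target above 1, donor below 0) are rejected with
the violated bound named.

Because only cycle 1 differs between arms and propagation is linear,
every per-cycle occupancy difference between intervention and control
scales exactly with (m − 1); the 1.2 scenario is exactly half the 1.4
scenario. The test suite asserts this identity to float precision.

### Profile aggregation

Published transition matrices for ageing cohorts are often reported on
a fine disability-profile scale (e.g. the 14 Iso-SMAF profiles plus
long-term-care facility). `aggregate_profiles` collapses such a matrix
into the model's coarse states: destination probabilities are summed
over each coarse group, and when several fine profiles share one
coarse source state their rows are combined as a weighted average
(caller-supplied occupancy weights; equal weights by default). The
weighted average preserves row-stochasticity and reduces to plain
destination summing for singleton groups. The original occupancy
weights used to build the shipped matrix are not recoverable, which is
why they are exposed rather than guessed; groups for which no weight
is supplied fall back to equal weighting so that a singleton group
never degenerates to an all-zero weight vector.

## Economic comparison

For two strategies the package reports ΔQALY and ΔCost over the
horizon. A strategy *dominates* when it has at least as many QALYs and
no higher costs with one inequality strict; otherwise the ICER
ΔCost/ΔQALY is reported and classified against Swedish
willingness-to-pay bands: low ≤ 11,000 €/QALY, moderate ≤ 55,000,
high above. Deterministic sensitivity analysis re-runs the pipeline
for scenario overrides of the effect multiplier and/or per-person cost
against a shared control arm; no probabilistic sensitivity analysis is
implemented.

The per-person intervention cost can be built from ingredients:
`(contact hours + visits × travel/admin hours per visit) × wage +
technical aids`. With the default 0.5 h travel/admin, 28.5 €/h wage
and 26 € aids, 3 visits/2 contact hours give 125.75 € and 12
visits/12 hours give 539 € — close to, but not exactly, the 128 € and
546 € the shipped configuration charges, whose exact ingredient
breakdown was not published. The shipped config therefore uses the
published totals directly.

## Microsimulation oracle and synthetic panels

`simulate_individuals` draws individual annual state trajectories from
a transition matrix (vectorised inverse-CDF sampling, numpy
`default_rng`, explicit seeds everywhere). It serves two purposes:

1. **Oracle.** Mean occupancy over n subjects converges to the cohort
   trace; at n = 10^6 the suite requires agreement within 3 binomial
   standard errors per state and cycle, and mean discounted QALYs
   within Monte Carlo error of the cohort totals.
2. **Panel generator.** Panels emulate the structure of real
   longitudinal ageing cohorts (annual observations, absorbing death)
   serialised as long-format CSV (subject, cycle, state). They do not
   emulate real-data features such as interval censoring, dropout
   other than death, misclassification, or age-varying transition
   rates — passing recovery tests therefore demonstrate estimator
   correctness under the model, not robustness to those artefacts.

`estimate_transition_matrix` is the standard count-based
row-normalised estimator pooled over subjects and cycles, with
absorbing rows forced to unit self-transitions. Non-absorbing states
never observed as a source are returned as `undefined_rows` on the
estimate (their rows carry a flagged self-loop placeholder so the
matrix object stays valid); `require_complete()` turns the flag into
an error. Parameter recovery is checked at 200,000 subjects × 4 annual
cycles (max entrywise error < 0.005) and the 1/√n error decay is
checked across two panel sizes; recovery panels start uniformly over
the living states so every row is observed.

## Numerical choices

- Row sums must equal 1 within 1e-9; entries outside [0, 1] by more
  than 1e-9 are rejected, while sub-tolerance float overshoot from
  sums/averages is clipped.
- An optional repair mode renormalises rows off by at most 0.005 —
  the worst case of a matrix published at two decimals — and logs the
  adjustment; larger deviations still fail validation.
- State order is canonical (mild, moderate, severe, total, death);
  all I/O is label-keyed, so permuted configs load to identical
  results and are never trusted positionally.
- Per-100 cohort counts are half-up rounded from 100 × occupancy.
- CSV artifacts serialise at full float precision; the human-readable
  report rounds QALYs to 3 decimals and euro to integers.
- Currency arithmetic is plain floating point; no inflation indexing.

## Reproduction accuracy and known limitations

With the shipped inputs the package reproduces the published QALY
quantities to the printed precision: control 2.211, intervention
2.263, ΔQALY 0.052 (0.026 at effect 1.2), the per-100 cohort counts
(17 vs 12 recovered to moderate after year 1; 25 vs 22 in
mild/moderate after year 2), about 3 additional life-years per 100
persons over years 6–8, and the 19-day full-health equivalent of the
QALY gain.

Costs do not reproduce as closely: the computed control-arm 8-year
total is ≈ 101,870 € against the published 94,982 €, and the saving
≈ 2,588 € against 2,410 € (both ≈ 7% high). The transition matrix is
published rounded to two decimals and the original spreadsheet's cost
discounting cannot be reconstructed exactly, so a discrepancy of this
order is expected; tests assert costs within ±10% and assert
unconditionally that the intervention dominates (more QALYs, lower
costs) in every scenario. The discrepancy is reported, not absorbed
into the inputs.

Other limitations: fixed one-year cycles (no continuous-time or
hazard modelling), a fixed horizon rather than lifetime or
gender-specific life expectancy, deterministic sensitivity analysis
only, and utilities/costs treated as known constants.

## Problem sizes

The deterministic pipeline is an 8-step, 5-state recurrence and runs
in microseconds. The microsimulation checks use 10^6 subjects × 8
cycles (oracle equivalence) and 200,000 × 4 (parameter recovery),
each completing in a few seconds; the acceptance script's logged
cross-check uses 200,000 subjects.
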