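# Methods

## Decision problem and structure

The model compares two strategies for adults aged 45–84 who would
otherwise undergo primary total knee replacement (TKR) in the index
year:

* **usual care** — primary TKR for the whole cohort in year 1;
* **intervention** — a 12-week structured education and exercise
  therapy program, with an annual probability of converting to TKR
  afterwards (0.26 in year 1, 95% CI 0.14–0.38; 0.08 each later year,
  95% CI 0.03–0.21), applied uniformly across pain states, ages and
  sexes.

It is a cohort model: persons are continuous masses, split over eight
(age band × sex) strata, each with its own starting age (band lower
bound + 5 by default), baseline pain-state mix, transition rows,
revision hazards and utilities.  Health states are the EQ-5D-5L pain
domain (*no/mild*, *moderate*, *severe/extreme*) plus absorbing death.
Cycles are annual with half-cycle (trapezoidal) correction; costs and
outcomes are discounted at 5% per year.

### Expanded state space

Because revision risk and post-surgical excess mortality depend on time
since the primary procedure, the engine runs on an expanded space:

* `pre(origin, current)` — program participants; the origin state is
  retained because their utility is *baseline utility of the origin plus
  the incremental utility of the origin → current transition* (this is
  how a program population with higher baseline quality of life is
  reconciled with registry-based surgical utilities);
* `post_primary[k](pain)` and `post_revision[k](pain)` with
  `k = 1..20` years since the *primary* operation; hazards are held at
  the year-20 value beyond the last tunnel;
* `dead`.

### Within-cycle event order

Fixed as: (1) death — all-cause probability `q(age, sex)` times the
years-since-surgery excess ratio for post-surgical states, capped at 1;
(2) surgery among survivors — converters receive the post-operative
pain transition *from their current state* and enter `post_primary[1]`;
(3) revision among post-primary survivors at the year-`k` hazard (pain
state unchanged, one revision per person, no re-revision).  Death
before surgery means no procedure is paid for.  Everyone alive at the
maximum age (100) dies at the end of that cycle, which makes the
lifetime horizon finite.

Pain dynamics are deliberately sparse, following the sources' designs:
the surgical transition is a single 6-month post-operative assessment
carried forward, and the program transition is a single 12-month
assessment applied once, in cycle 1, to non-converters; thereafter pain
states persist except through conversion or revision.  Later converters
therefore pass through *two* transitions (program, then surgery), which
can leave them marginally healthier than the usual-care arm — a small
genuine feature of this structure visible as a slight late-horizon
upturn in the INMB curve.

## Economics

* Discounting: cycle-1 flows undiscounted, `(1+r)^-(t-1)` thereafter.
  The convention is fixed and documented because only the rate (5%) is
  conventionally reported; all identity-based checks are robust to it.
* Utilities accrue on the trapezoid of start- and end-of-cycle
  occupancy; in cycle 1 the start-of-cycle utilities are the
  pre-intervention baseline values.  Event flows are charged at full
  value in the event cycle: procedure costs, and a 0.28 one-off
  disutility for the revision cycle; a 0.10 chronic disutility is baked
  into the revised state's utility (both carry an assumed SE of 25%).
  The trapezoid phases the chronic decrement in over the revision cycle.
* The program cost (A$1 500) is a one-off charged to every intervention
  enrollee at the start of year 1; converters additionally pay the
  primary-TKR cost (weighted mean A$24 607; public A$20 955 / private
  A$25 435) in their conversion cycle; revisions cost A$43 125 weighted
  (A$43 233 / A$43 078).  When explicit weighted means are absent from a
  bundle they are derived from the hospital mix (26.9% public); the
  synthetic bundles do this so that hospital-type subgroups aggregate
  exactly to the base case.
* `INMB = λ·ΔQALY − ΔCost` at λ = A$28 033 per QALY, reported per
  person; the ICER is suppressed when both increments are negative
  (south-west quadrant), where its sign is uninterpretable.  A$ → USD
  at 0.6947.
* The horizon sweep truncates the cumulative discounted streams at every
  horizon `h` and reports the largest `h` with INMB ≥ 0.

## Sensitivity analyses

One-way DSA bounds: reported 95% CIs for the conversion probabilities;
the stated A$750–A$3 000 range for the program cost; ±1.96 SE with a 15%
SE for surgical costs and 25% for revision disutilities; ±1.96 SD on the
log scale for mortality multipliers (0.05) and excess ratios (0.1); a
±1.96 × 0.025 additive shift for the program's incremental utilities.
The two conversion probabilities are separate parameters, mirroring how
they are reported.  Bounds that would leave [0, 1] are clipped with a
warning.

The PSA (default 1 000 draws) jointly samples: Dirichlet baseline
mixes and transition rows parameterised by their pseudo-counts; Beta
conversion probabilities moment-matched to mean and CI with
SE = (hi − lo)/3.92; Beta revision hazards at an effective sample size
of 1 000 per stratum; Gamma costs and revision disutilities
(shape = (mean/SE)²); log-normal excess ratios and per-sex mortality
multipliers parameterised so their *mean* equals the base ratio.  Every
fitted family reproduces its base-case mean analytically to 1e-6
relative, so the base case is the expectation of the input draws.
Random streams are keyed by `(seed, draw index, parameter path)`, so
adding a parameter never reshuffles existing draws; zero-dispersion
settings degenerate every family to a point mass, reproducing the base
case exactly.  Summaries use percentile (2.5/97.5) intervals, CE-plane
quadrant fractions, and a CEAC over 0–2λ in 101 steps.  State utilities
themselves are held fixed in the PSA (their uncertainty is examined in
the DSA); stratified Dirichlet rows are sampled independently across
strata.

## Synthetic input bundles

The real inputs are registry and statistical-agency tables that cannot
be shipped, so `oamodel.synthetic` generates structurally faithful
stand-ins:

* population counts and procedure rates per stratum scaled to a
  national cohort of ~60 700 (rates rise with age, peak at 65–74,
  slightly higher in women);
* Gompertz mortality `q(age) = 1 − exp(−a·e^{b·age})` with `a`
  calibrated by bisection so life expectancy at 65 is 22.0 y (women)
  and 19.0 y (men);
* excess-mortality ratios 0.55 (years 1–4), 0.80 (5–9), 1.00 (10–12),
  1.25 (13+): protective early, elevated late;
* surgical transitions concentrating in no/mild pain (≥ 65% from every
  state) and program transitions improving less; revision hazards with
  an early peak decaying to a ~0.25%/year floor, higher at younger ages;
* baseline mixes around (0.20, 0.50, 0.30) with more no/mild pain in
  men and in private hospitals; utilities around (0.72, 0.55, 0.35)
  baseline and (0.85, 0.68, 0.48) post-surgical, with a small age
  decrement; program incremental utilities equal to the baseline
  utility difference of the transition plus a 0.03 uplift.

All dispersion and level choices were made once, as plausible national
magnitudes, before any downstream result was inspected.  Three profiles
exist: `paper_like` (above), `null_effect` (identical-row shared
transitions, aligned utilities, unit excess ratios, zero revision
disutilities — the arms then differ in costs only, which the tests
exploit as an exact symmetry), and `extreme_benefit`.

What the generator does **not** emulate: true registry sampling noise
structure, between-year trends, waiting-list dynamics, contralateral or
other-joint surgery, and the published tables' exact values.  Passing
tests therefore demonstrate correctness of the *machinery* (conservation,
identities, oracle equivalence, distribution calibration), not numerical
replication of the published cohort totals; those are exercised as
arithmetic-identity checks on the printed values packaged in
`data/table2.json`.

## Verification strategy

* **Microsimulation oracle.** An individual-level simulation with the
  identical event logic; the cohort model is its exact expectation, and
  the suite requires agreement within 3 Monte Carlo SEs at 200 000
  individuals for costs and QALYs in both arms.
* **Closed forms.** Discount factors; cumulative conversion
  `1 − 0.74·0.92^(n−1)`; trapezoid = exact integral for linear
  occupancy; geometric life-year sums under constant mortality.
* **Identities.** Mass conservation every cycle (1e-9 relative);
  one-cycle operators row-stochastic to 1e-12; INMB identity to machine
  precision; exclusive subgroups summing to the base case (1e-6).
* **Published-number consistency.** Per-person × n = total, the INMB
  identity, partition additivity and currency conversions over the
  printed tables at a 0.1% rounding tolerance with floors reflecting
  the printed precision (whole dollars; the INMB identity inherits up
  to `0.5·λ/n + 0.5` from half-unit rounding of printed totals).
  Hospital-type subgroups are excluded from the published additivity
  check: the source produced them with type-specific inputs and they do
  not aggregate exactly to its base case.

## Numerical and scale choices

Acceptance runs use the full eight-stratum bundle (one model run
≈ 0.25 s), a 1 000-draw PSA and a 200 000-individual microsimulation.
Tests that rerun the model many times use a two-stratum, age-75-capped
bundle.  Tunnel depth is 20 years (registry revision reporting horizon);
maximum age 100 (life tables terminate near there).  Degenerate inputs —
empty subgroups, zero cohorts, zero rates — return zero-valued results
rather than errors; invalid bundles fail validation with the offending
file and cell named.

## Known limitations

Single revision per person; pain states static between events; program
effectiveness assumed homogeneous across strata (as reported, for lack
of stratified data); no societal-perspective costs, waiting-list
dynamics or other-joint surgery; the conversion probability beyond year
2 extrapolates a 2-year trial; synthetic bundles are plausible but not
registry-accurate, so absolute synthetic outputs should not be read as
national estimates.
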