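# Methods

This note documents the models and procedures `xenoresponse` implements,
the conventions chosen where the underlying study designs leave room, and
what the synthetic test-bench does and does not establish about real data.

## Study frame and units

All volumes are mm³; time is in integer study days with day 0 the day of
randomization / first dose. Negative days (pre-randomization measurements)
are accepted and consulted only as an initial-tumor-volume fallback. The
default dosing layout is one 14-day cycle with cisplatin on day 1 and
etoposide on days 1–3; "end of dosing" defaults to the last administered
dose day of the last completed cycle (day 3 for a single cycle), with the
trajectory evaluated at the nearest daily value on/after that day. Input is
a long (tidy) table only; wide tables must be pre-melted. Caliper
length/width → volume conversion is out of scope: the package consumes
volumes.

## pRECIST scoring

**ITV.** The day-0 volume when observed, else the latest measurement at
day ≤ 0, else (with a warning) the first measurement.

**Tx.** The first day the daily-interpolated series strictly exceeds
ITV · (1 + 300/100). When the threshold is never reached, Tx is
extrapolated by ordinary least squares of the *raw observed measurements*
from day 0 onward — not the interpolated grid, which would only dilute the
fit with derived points. At least two observations are required; a fitted
slope ≤ 0 yields Tx = +∞. An extrapolated crossing beyond 10× the study
length is also treated as +∞: a near-flat fit can place the crossing
centuries out, and a TGD built on such a number is noise.

**TGD.** Tx_treated / median(finite vehicle Tx). The median over an even
number of values is the midpoint mean. A consequence used as a test
invariant: when all vehicle Tx are observed, the median of the vehicle
arm's own TGDs is exactly 1.

**Doubling time.** DT = Δt · ln 2 / ln(V_last/V_first) from first and last
measurements; undefined without net growth. The DT entering the MCR rule is
the *vehicle-arm median* of per-animal DTs from the same model: a treated
animal's first/last volumes reflect the drug, not the tumor's intrinsic
kinetics, and the "maintained for one doubling time" criterion is about how
long an untreated tumor would have needed to double.

**Classification.** The ordered tree (MCR, CR, PR, SD, PD1/PD2) uses strict
">" at the 90/50/25% cuts and "≤" at the TGD 1.5 cut. Two conventions are
worth calling out:

- Classification is per animal, aggregated to the model by ordinal mean
  with exact halves rounded toward the worse call — conservative for
  response claims, and reduces to the obvious answer when all animals
  agree.
- SD requires the ≤25% condition both *at* the end of dosing and at every
  day *during* the dosing window, so a transient spike inside the window
  cannot masquerade as stable disease. This is an interpretation (the rule
  text fixes only the end-of-dosing check) and is flagged in the score
  record.

An undefined doubling time makes MCR unreachable; CR is returned with a
warning in the record. Vehicle animals are not assigned calls; they define
the reference growth only.

## Growth-curve preprocessing

Alignment anchors each animal at the earliest measurement inside
50 ± 10 mm³, or at the first measurement when it already exceeds 60 mm³;
measurements before the anchor are dropped (recorded in output provenance),
later in-window measurements are ordinary data. A series with no in-window
point and a first measurement ≤ 60 mm³ has an ambiguous start and is an
error rather than a guess.

"Linear regression across each two available measurements" is exact chord
interpolation — a two-point regression *is* the line through the points —
so observed days keep their raw values bit-exactly and second differences
vanish between observations. Series extension carries the final observed
value forward (the final measurement is the maximum in the intended
resection setting; when noise makes them differ the *last* value is carried,
with `carry="max"` available). Extension never alters existing values and
is idempotent. Cohort profiles are per-day mean and sample SD (n−1); SD is
reported missing at n = 1.

## Survival and association statistics

- **Time-to-event**: resection day (event); otherwise first daily crossing
  of 800 mm³ (event — the explicit non-censoring rule for animals that
  grew out instead of being resected); otherwise censored at the last day.
- **Kaplan–Meier / log-rank** are implemented from first principles
  (product-limit; hypergeometric O−E with the standard events-before-
  censorings tie convention; chi-square reference with k−1 df) and are
  cross-checked against lifelines in the test suite.
- **Fisher 2×2** uses the probability-mass two-sided rule — the sum of
  hypergeometric probabilities ≤ the observed table's, with 1e−7 relative
  tolerance on the comparison — computed in exact integer arithmetic
  (binomial-coefficient weights), so the test suite can compare it against
  enumeration for every table with total ≤ 40.
- **Rank-sum**: the exact mode computes the permutation distribution of the
  mid-rank sum over all C(m+n, m) labelings via a generating-function count
  (equivalent to full enumeration, without the factorial blow-up), two-sided
  by distance from the null mean; the approximate mode uses the normal
  approximation with tie-corrected variance and a 0.5 continuity
  correction. `auto` switches to approx above 10,000 labelings; exact is
  refused above a configurable cap (default 10⁷ labelings).
- **Dunnett adjustment** is seeded Monte Carlo from the exact null
  structure (shared control mean, shared chi-square variance estimate),
  which reproduces classical Dunnett in the balanced case to ±~0.002 at
  the default 10⁵ draws; scipy's quadrature implementation serves as the
  test oracle, not the implementation. Zero pooled variance with equal
  means returns p = 1 (the statistics are 0); with unequal means it is an
  error, since no finite t exists.
- **ANCOVA slope comparison** pools animals as independent observations and
  F-tests the group × day interaction via nested OLS fits (statsmodels).
  The default volume transform is the cube, y = x³, per the source
  procedure's literal description; `cube_root`, `log` and `identity` are
  offered because cubing is unusual (it *amplifies* late-curve variance —
  the plausible intent was linearizing diameter-like growth), and every
  report names the transform used. A zero-residual degenerate fit reports
  p at the smallest positive float with an explanatory note.
- **Power design** iterates the noncentral-t power function
  (df = 2n−2, noncentrality d√(n/2)) to the smallest n per group reaching
  the target; d = 1.5 at α = 0.05 and 70% power gives n = 7, verified by
  simulation in the acceptance checks.
- **Proportions** are reported exactly and rounded half away from zero, the
  convention that maps 15.69% to the printed "16%".

## Synthetic cohorts

The generator emulates the study design the analysis assumes: initial
volumes spread deterministically (evenly, descending) over 200–300 mm³ and
split between arms by serpentine randomization (A,B,B,A,…; of the two
phases the one with the smaller arm-mean difference wins); exponential
growth at 0.20/day (3.5-day doubling, an aggressive SCLC-like xenograft)
with a lognormal 10% CV across animals; Mon/Wed/Fri measurements;
termination at the first observation ≥ 1200 mm³ or at the 28-day horizon;
multiplicative lognormal measurement noise with a 10 mm³ detection floor.

Treatment acts per cycle as an instantaneous fractional volume kill at the
first dose day and/or a fractional growth suppression over a window. The
effect model includes an onset delay (days after dosing before suppression
begins): delayed-onset cytostasis is the natural mechanism by which a tumor
can exceed +25% growth by day 3 and still show a large growth delay — the
PD2 phenotype. The six presets place each class well inside its region:
PD1 mild early suppression (TGD ≈ 1.14), PD2 delayed full cytostasis
(TGD ≈ 2.7), SD a 15% kill with cytostasis through the dosing window, PR a
70% kill (nadir ≈ 37% of ITV), CR a 95% kill with immediate regrowth
(below 10% of ITV for ~2 days, under one doubling time), MCR a 95% kill
with 24-day cytostasis.

Determinism: every animal's RNG stream derives from the master seed plus a
stable hash (CRC-32) of its id, so adding animals never perturbs existing
trajectories. "Zero noise" in the preset-fidelity guarantee means the fully
deterministic regime — measurement noise *and* the biological rate CV both
zero — since per-animal rate variation is itself a noise source that can
move a boundary class (most visibly PD1's TGD) across a cut in a small
fraction of animals; passing `rate_cv` explicitly overrides this.

What the synthetic bench shows — and what it does not: trajectories are
piecewise-exponential with independent multiplicative noise, so passing
tests demonstrate the *scoring and statistics* are correct under the
assumed generative structure. Real caliper series have serially correlated
errors, Gompertz-like deceleration near large volumes, missed visits and
welfare-driven informative dropout; none of these are emulated, and recovery
rates measured here do not transfer to real data as accuracy claims.

## Problem sizes and seeds

The built-in verification runs use sizes chosen to make their Monte-Carlo
margins comfortable: 10,000 random trajectories for classifier/oracle
agreement, 200 treated animals per class at 10% noise for recovery (point
estimates ≥ 95% against the 90% bar), 500–1,000 simulated cohorts for TGD
self-normalization, 2,000 replicates for log-rank null uniformity, and 10⁵
replicates for the power simulation. All are seeded and deterministic.

## Known limitations

- No mixed-effects or Gompertz growth modelling; the growth model is
  intentionally the simplest one consistent with ratio-based endpoints.
- The ANCOVA treats repeated measures of one animal as independent points;
  with few animals per arm the interaction p is anti-conservative.
- Fisher and rank-sum exactness is enumeration-based and so bounded by the
  configured caps; beyond them the normal approximation is used.
- The pRECIST tree is evaluated on the daily-interpolated series; a kill
  between two observation days is only seen through its effect on the next
  observation.
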