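# Methods

## The randomization model

A single-case experiment fixes, a priori, a randomization scheme: the set of
admissible assignments of conditions to measurement occasions.  Under the
null hypothesis that the treatment is ineffective, the measurement series is
exchangeable across that set — the data would have been identical under any
other admissible assignment.  The randomization test therefore evaluates the
chosen statistic T at every admissible assignment (or at a uniform sample of
them) and reports

p = #{ assignments a : T(a) as-or-more-extreme-than T(observed) } / #set,

with the observed assignment always counted in both numerator and
denominator.  This makes p ≥ 1/R exact and the test valid by construction:
under the null, P(p ≤ α) ≤ α for every α.  Right, left and two-sided tails
are supported; the two-sided test uses the absolute-difference statistic
rather than tail doubling, because the discrete reference distribution is
generally asymmetric.

### Admissible sets per family

* **Phase designs** with k phases, n occasions, minimum phase length m: the
  assignments are the compositions of n into k ordered parts each ≥ m, so
  R = C(n − km + k − 1, k − 1) (stars and bars after reserving m occasions
  per phase).  An ABAB design with n = 24 and m = 3 has R = 455.
* **Completely randomized** alternation designs fix per-condition totals;
  the reference set is the multiset permutations of the label pool.  An
  `unrestricted` variant gives the coin-flip scheme (|conditions|^n); the
  fixed-totals scheme is the default because it is the one used in the
  worked single-case literature, and the two are not equivalent.
* **Alternating treatments designs** additionally cap the maximal run of
  identical labels across the whole sequence (no block structure).  The
  count uses dynamic programming over (remaining totals, last label, current
  run length); infeasible totals yield an empty set of size 0, not an error.
* **Randomized block designs** concatenate independent within-block
  permutations: R = (t!)^b.
* **Multiple baseline designs** assign each of u distinguishable units a
  start day in a window of width W.  With pairwise-distinct starts
  R = W!/(W − u)!.  A minimum stagger s generalizes distinctness (s = 1):
  sorted starts with consecutive gaps ≥ s biject onto u-subsets of a window
  of width W − (u − 1)(s − 1), so R = u!·C(W − (u − 1)(s − 1), u).  This
  closed form is cross-checked against brute-force enumeration in the tests.
* **Changing criterion designs** randomize each phase boundary within its
  candidate list; R is the product of the list sizes (2⁹ = 512 for nine
  binary boundaries).

Enumeration order is canonical lexicographic (on the change/start vector or
the label sequence).  Samplers are exactly uniform: constructive bijections
where available (compositions ↔ subsets, permutations, products, the stagger
gap bijection) and rejection from an exactly uniform superset for the
run-limited alternation scheme.  Monte Carlo reproducibility depends only on
the seed, never on enumeration order.

## Test statistics

All statistics address the *level* of the series (trend, variability,
overlap, immediacy and consistency are out of scope):

* `phase_mean_diff_{BA,AB,abs}` — sum of B-phase means minus sum of A-phase
  means (means within maximal runs), its negation, or its absolute value.
* `alternation_mean_diff_AB` — pooled mean of all A occasions minus pooled
  mean of all B occasions.  Pooling across occasions (not per run) is what
  distinguishes the alternation statistic from the phase statistic.
* `mbd_mean_diff` — mean over units of (post-start mean − pre-start mean).
  For a single two-phase unit this reduces exactly to the phase statistic,
  which the tests use as a cross-check oracle.
* `ccd_mad` — mean absolute deviation of each measurement from its phase
  criterion, Σ|C_phase(t) − y_t|/N; for interval criteria [lower, upper] the
  deviation is zero inside the band and the distance to the nearer bound
  outside.  Zero means perfect adherence, so the test is left-tailed.

Statistics are computed in full floating precision; two-decimal rounding is
purely a display convention.  A worked consequence: the printed rounded
ABAB phase means (29.67, 63.67, 54.33, 85.67) give a statistic of 65.34,
while the unrounded raw data behind them gave 65.33 — the tests target 65.34
because only the rounded means are reproducible inputs, and the one-cent
discrepancy is a rounding artefact, not an implementation defect.

### The changing-criterion baseline criterion

Under the `median_of_baseline` rule the baseline criterion is computed once
from the realized baseline segment and held fixed across all reference
assignments.  Recomputing the median per candidate assignment would make the
criterion — and hence the hypothesis — assignment-dependent.  This is a
design choice: the convention in worked examples fixes the criterion from
the observed baseline, but no authority addresses the candidate-assignment
case explicitly.

## Numerical conventions

* Two statistic values tie when |a − b| ≤ 10⁻⁹·max(1, |a|, |b|).  Phase
  means are ratios of sums; demanding exact binary equality would
  misclassify algebraically tied assignments.
* Monte Carlo references draw n_mc − 1 assignments with replacement, add the
  observed, and use denominator n_mc.
* Exhaustive enumeration is refused above a configurable cap (default 10⁷
  assignments); `method="auto"` switches to Monte Carlo above R = 10⁴.
* Assignments that would leave a role without occasions are inadmissible by
  construction (minimum phase length ≥ 1), so no statistic divides by zero.
* Missing values are a hard construction error; imputation would silently
  change the reference distribution.

## Power

The smallest attainable p-value is 1/R, so a design with 1/R > α has zero
power at level α — fewer than 20 admissible assignments cannot reach
significance at the conventional 0.05.  `estimate_power` returns exactly 0
(zero variance, no simulation) in that case.  Otherwise each of n_sims
replicates draws a *true* assignment uniformly (design-consistent power; a
fixed-assignment mode exists for sensitivity checks), generates data
conditional on it, runs the test, and records rejection at α; the estimate
carries the binomial standard error √(p̂(1 − p̂)/n_sims).  Default
n_sims = 1000; inner tests are exhaustive when R ≤ 10⁴ and Monte Carlo
otherwise.

One property check deserves a note.  Wider stagger between multiple-baseline
start days should not reduce power, but comparing an exhaustive test at
R = 336 with one at R = 24 confounds the stagger effect with p-value
discreteness (attainable levels 16/336 vs 1/24).  The test therefore
compares the two stagger settings through Monte Carlo inner tests with a
common n_mc, giving both the same p-value resolution; the suite uses
3 units, 40 occasions, a 16-day window, stagger 1 vs 3, n_mc = 500 and
200 replicates.

## The synthetic-data generator

Real single-case datasets in this literature are typically published as
figures, not numbers, so every distributional check here runs on synthetic
series with known structure:

y_t = μ + δ·1[label(t) ∈ B-role] + trend·(t − phase start) + ε_t,

with ε_t a stationary AR(1) process: ε_1 ~ N(0, σ²) and
ε_t = φ·ε_{t−1} + N(0, σ²(1 − φ²)), so the marginal standard deviation is σ
for every φ and power comparisons across autocorrelation levels hold
marginal noise constant.  The within-phase trend restarts at each phase
change.  Changing-criterion series are generated around the phase criterion
(midpoint for interval criteria) with N(0, ccd_adherence_sd) adherence
noise; baseline occasions centre on the fixed baseline criterion when one is
given and on μ otherwise (the median rule cannot seed its own generation).
Defaults: μ = 0, δ = 1, σ = 1, φ = 0, trend = 0.

Noise is Gaussian by design: randomization tests are distribution-free, so
the generator's job is controlled structure, not realism.  What the
generator does **not** emulate — bounded or ordinal outcome scales, session
effects, heavy tails, missingness — bounds what passing tests show about
real data: they validate the combinatorics, the exactness of the inference,
and the qualitative power behaviour, not robustness to every data pathology.

The suite's canonical shapes mirror the four families at realistic sizes:
ABAB with 24 occasions and minimum 3 per phase; an alternating treatments
design with 6 occasions, 3 + 3 and max run 2; a multiple baseline with
5 units, 55 occasions and starts on days 15–36; a changing criterion design
with nine treatment phases, two candidate change moments per boundary and
criteria stepping down 5 units per phase.  Simulation-heavy checks
(null-validity at 2000 replicates, power curves at 1000) use a 16-occasion
ABAB variant (R = 35) so the whole suite stays fast while R remains above
the zero-power threshold.

## Known limitations

* Factorial decomposition of compound phases (e.g. A-B-A-BC interaction
  analysis) is not provided; compound labels are just labels.
* No asymptotic permutation approximations, confidence intervals by test
  inversion, analytic power formulas, or optimal-design search.
* Blocking is limited to equal-size blocks with each treatment once per
  block; no adaptive or response-guided randomization.
* Trend/variability/overlap statistics and standardized single-case effect
  sizes (NAP, Tau-U, SMD) are out of scope.
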