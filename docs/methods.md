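# Methods

## The evidence triplet

For a two-arm binary-outcome trial summarised as a 2×2 table with cells
(a, b, c, d), arm sizes n1 = a+b, n2 = c+d and N = n1+n2, the package
computes three complementary quantities.

**Significance.** Two-sided p-value with alpha fixed at 0.05 (a tie at
exactly 0.05 counts as significant). Two tests are implemented:

* Fisher's exact test, two-sided by the minimum-likelihood rule: the sum
  of hypergeometric point probabilities, over all tables with the observed
  margins, that do not exceed the observed table's. Point probabilities
  are compared as exact integer numerators (all share the denominator
  C(N, m)), so tables whose p is an exact rational such as 1/20 classify
  correctly at the alpha boundary — a real concern inside the fragility
  search, which probes tables near p = 0.05 by construction. The final
  division is the only floating-point rounding step.
* Pearson's chi-square on 1 df without continuity correction. A zero
  margin makes the statistic undefined; such tables are reported as p = 1
  with an explicit degeneracy flag rather than silently.

Which test runs depends on the context. Simulated trials use Fisher when
N ≤ 50 or any cell is below 5, chi-square otherwise. Empirical
(published) tables use chi-square only when N > 5000 and every cell is at
least 50, and Fisher everywhere else. The rule is a property of the
current table, so it is re-applied after every fragility toggle (a toggle
can move a cell across the small-cell boundary; when that switches the
test mid-search it is logged at debug level).

**Fragility.** The fragility index FI is the minimum number of
single-participant outcome toggles, confined to the *modified arm*, that
moves the significance classification across 0.05 — in either direction:
significant tables are toggled until nonsignificance, nonsignificant
tables until significance (a reverse fragility index, computed by the same
algorithm, so stability is defined for every trial). The modified arm is
the fewer-events arm; an event-count tie goes to the smaller arm, and a
full tie deterministically to arm 1. Toggles change only the
event/non-event split inside that arm; arm sizes are invariant. The
search scans outward from the observed split one toggle at a time,
considering both monotone directions (all toggles add events, or all
remove events) and taking the first classification flip; mixed-direction
sequences cannot beat the best monotone sequence because the reachable
tables form a one-parameter family in the arm's event count. When no
achievable split of the modified arm flips the classification the index
is capped at n_mod (MFQ = 1, maximally stable) and flagged.

The modified-arm fragility quotient MFQ = FI/n_mod normalises FI to the
toggled arm so that unequal allocation does not distort the scale; FQ =
FI/N is also reported. Fragile means MFQ ≤ 0.10 (boundary inclusive) —
under 1:1 allocation this coincides with FQ = 0.05, mirroring the 5%
significance convention. The threshold is a heuristic classification aid,
not a normative standard.

**Robustness.** The risk quotient RQ = |ad − bc| / (N²/4) measures, on a
0–1 scale, how far the table sits from the neutrality surface ad = bc
(equal event odds in both arms). The numerator is computed in exact
integer arithmetic. Weak means RQ < 0.075 and strong RQ ≥ 0.227; the two
cut points are the 33rd/67th percentiles of the RQ distribution from an
independent prior simulation of one million trials over realistic design
parameters, and are consumed here as constants (`RobustnessThresholds`
allows overrides; the deriving simulation's sampling scheme is not
re-implemented).

**Patterns.** Five mutually exclusive, exhaustive labels:
concordant-positive (p ≤ 0.05, MFQ > 0.10, RQ ≥ 0.227),
significant-fragile-weak (p ≤ 0.05, MFQ ≤ 0.10, RQ < 0.075),
concordant-null (p > 0.05, MFQ > 0.10, RQ < 0.075), and residual
significant / nonsignificant categories. The two residuals make the
partition total, so pattern counts always sum to the number of trials —
a tested invariant.

## The Monte Carlo benchmark

`reference_grid()` crosses five total sample sizes (60, 100, 200, 400,
800), three allocation ratios (1:1, 2:1, 3:2, intervention:control), four
control event rates (0.05, 0.10, 0.20, 0.40) and six true relative risks
(1.00, 0.90, 0.80, 0.70, 0.60, 1.10) — 360 scenarios, 2,000 replications
each at full scale (720,000 trials; 120,000 null). Design choices:

* The true relative risk multiplies the control event rate, so the
  intervention-arm event probability is CER × RR (max 0.44 over the grid,
  always a valid probability).
* Arm 1 is the intervention arm and receives the larger share under
  unequal allocation. Non-integer splits round half-up on arm 1
  (N = 100 at 2:1 → 67/33). Both conventions are recorded in the run
  metadata columns so sensitivity to them can be audited.
* Event counts are independent binomials per arm; every simulated table's
  arm sizes equal the allocation split exactly (tested).
* Seeding: one master seed; scenario i uses
  `SeedSequence(master, spawn_key=(i,))`, so individual scenarios can be
  re-run independently and a full run is bit-reproducible (tested).
  A scenario's own `seed` field, when set, takes precedence.
* Each simulated trial is analysed with the simulation-context test rule.
  Triplet results are memoised on cell counts within a run, and p-values
  globally; replicated scenarios revisit few distinct tables, which is
  what makes full-grid runs take seconds rather than hours.

The simulation generates unfiltered random trials: no publication bias,
stopping rules or selective reporting are modelled. Its purpose is to
calibrate expectations — e.g. that among *significant* null trials the
concordant-positive pattern is rare (~1.4%) while the
significant-fragile-weak pattern is common (~32%) and nearly flat in the
true effect size — not to describe any published literature.

## Synthetic trial collections

`generate_fixtures` produces a deterministic stand-in for a heterogeneous
literature sample: trial sizes log-uniform (default 20–2,000), control
event rates uniform (0.05–0.50), allocations drawn from {1:1, 2:1, 3:2},
and true effects from a relative-risk mixture (default 40% null, the rest
spread over RR 0.40–1.50). The output is checked to contain all five
patterns, retrying with an incremented sub-seed a bounded number of times
before erroring. These collections exercise the empirical-analysis
pipeline end to end; they do not emulate publication filtering, extreme
trial sizes (hundreds of thousands of participants), or domain structure,
so prevalences computed from them characterise the generator, not any
published corpus.

## Problem sizes and numerical choices

The test suite and the reproduction script run the benchmark at reduced
replication counts — 1,000 reps/scenario for the null sub-grid, 500 for
single-RR sub-grids — which the memoised analysis completes in seconds
while keeping binomial standard errors well inside the comparison
tolerances for most quantities (the null sub-grid at 1,000 reps yields
roughly 2,400 significant trials, giving a standard error near 0.25
percentage points on the CP prevalence). Wilson intervals use the exact
normal quantile for the stated level; the interval bounds at k = 0 and
k = n are snapped to exactly 0 and 1. The exact binomial enrichment test
is two-sided by the minimum-likelihood rule (one-sided variants exist in
the library). Fold elevations are reported both as raw ratios and as a
display variant computed from percentages pre-rounded to one decimal,
matching how folds are conventionally quoted next to one-decimal
percentages.

## Limitations

Only independent-sample two-arm binary outcomes are supported;
matched-pair and crossover designs are out of scope, as are extensions of
the neutrality-distance construction to continuous, ordinal, survival or
correlation endpoints. The robustness cut points are inherited constants,
not re-derived. The triplet stratifies the statistical evidence in a
single table; it makes no claim about truth, causality or replication
probability, and prevalences computed on synthetic collections do not
estimate those of any real literature.
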