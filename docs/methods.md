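# Methods

This note documents the models and procedures implemented in `cogrehab`,
the defaults they ship with, and what the synthetic-patient tests do and
do not demonstrate.

## Profiles and the profile language

A profile schema fixes an ordered list of domain/subdomain labels and,
per label, a finite value grid `(min, max, step)`. The classical
formulation of profile dynamics uses natural-number components; clinical
training scales use half-steps on 1–10. One representation serves both:
the grid is explicit per label, integers (`step=1`) by default and
`(1, 10, 0.5)` for training work, and atom constants may be non-integers
(7.5 must be expressible on the half-step scale). Linguistic labels
(e.g. marital status) are supported by mapping category names to grid
integers at schema load; the semantics are unchanged.

Sentences are built from atoms `term {=,<,>,<=,>=} constant` where terms
are labels closed under negation and sum, with `!` and `&` primitive;
`|`, `->`, `<->` desugar into the primitive pair and `<=`/`>=` keep
direct semantics (tests verify they match their negation forms). The
concrete ASCII surface syntax (`&`, `!`, `|`, `->`, `<->`) is this
package's choice; the underlying language fixes none. Comparisons use a
1e-9 tolerance because decimal grids are not binary-exact.

Model enumeration is exhaustive over the grid product, guarded by a cap
(default 200 000 points) with an explicit error above it. No quantifiers,
no infinite domains, no arithmetic beyond negation and sum.

## ACP aggregation

`Norm` is linear min–max normalization onto [0, 100] using each
sub-score's published range — the only normalization the source weight
table instantiates anywhere, and therefore the one fixed here.
Reverse-scored instruments (depression scales, the IAFAI incapacity
index) carry a `higher_is_better=false` flag and normalize flipped;
without this the weighted aggregation would mix "higher is worse" scores
into "higher is better" domains.

The shipped weight table stores the expert-elicited raw percentages
verbatim; renormalization to per-domain fractions happens at load. When
sub-scores are missing, the surviving raw percentages are renormalized
again — the stated missing-data rule — and a domain with no scorable
entry is reported absent, never zeroed or imputed. The raw percentages
are taken as given rather than re-derived from sub-score counts.

Two published cells differ from the exact renormalized values by one
final-digit rounding (the published table rounds so each row sums to
100.00): working-memory 17.13 (exact 17.135) and inhibition 79.88 (exact
79.8706). The package computes the exact values.

## Cognitive Status

Normative data are available per instrument total (not per item), as
strata keyed by socio-demographic criteria (age band, education years,
arbitrary extra keys). The expected score for a domain is the weighted
mean of the contributing instruments' group averages (weights: the
domain's per-instrument weight-table fractions). Two backends sit behind
`compute_cs`:

- `anchor` (default): `CS_k = 100 · ACP_k / (2 · expected_k)`, clipped to
  [0, 100]. This is the cross-multiplication rule anchored so that a
  patient exactly at the group average lands on 50; the clip is this
  package's addition (the rule alone can exceed 100 for strong patients
  in weak strata).
- `percentile`: normal-CDF placement of the ACP against the aggregated
  stratum mean/sd, for users who want literal percentile semantics.

A missing stratum raises an explicit error rather than falling back to a
global mean. The shipped normative table is synthetic (fabricated round
numbers, marked as such in its filename and description) and exists only
to exercise this machinery.

The simplified screening scheme maps five macro-domains onto 0–10: each
entry is min–max normalized to 0–10, each subdomain is the mean of its
available entries, each macro-domain the mean of its scorable subdomains.

## Task selection

The per-domain coverage distance works on a 0–10 axis (CS/10): 0 inside
the covered range, the gap to the nearest endpoint otherwise, capped at
10, and exactly 10 for an uncovered domain. The cap applies to near-miss
gaps as well as to absent coverage, keeping 10 the maximal value in all
cases. Multiple domains combine by priority-weighted sum — the
combination rule is a design choice here (the distance is specified
per-domain only) and is deliberately simple and overridable. Ranking is
deterministic: ascending score, ties broken by lexicographic task id.

Context filtering keeps tasks whose contexts intersect the preferred
daily-living contexts (an empty preference set is a no-op) and truncates
to the program time budget `sessions × minutes_per_session` using each
task's nominal duration (default 11 minutes, configurable per task). An
empty result raises rather than returning silently.

Initial parameterization: difficulty `d` is the training-weight-weighted
mean of the profile values over the trained domains, snapped to the
grid; each parameter interpolates linearly between its bounds at
`(d − grid_min)/(grid_max − grid_min)`. Anchoring at the grid minimum
(rather than at 0) ensures the scale floor maps to every parameter's
minimum and the ceiling to its maximum. Integer-bounded parameters are
rounded. Hard per-kind limits (search targets ≤ 12, ≤ 20 elements per
section, ≤ 8 sections; 2–12 sequencing steps; 2–60 items into ≤ 4
containers) are enforced both at model load and at parameter validation,
where violations are returned as data.

## Session adaptation

Defaults: lower threshold 50%, upper 71%, step 0.5 on the 1–10 half-step
grid. The band edges are treated strictly — performance < 50 lowers,
> 71 raises, anything in [50, 71] holds — which reproduces every
documented example while deciding the edge values deterministically (the
prose around the rule variously implies 50–70, 51–70 and >71).
Difficulty saturates at the grid bounds; saturation behaviour is this
package's choice. Adaptation is per task, the stated refinement over the
older session-global scheme; the session runner tracks one difficulty
trajectory per task.

The flow target (≈50–70% success) and the controller thresholds (50/71)
are kept as separate configurable values since nothing states they must
coincide.

Medals partition [0, 100]: none below 50, copper [50, 70], silver
(70, 90], gold (90, 100]. Hints halve the play's points; scoring never
goes negative.

MoCA-based initialization maps domain raw scores (maxima: attention 6,
memory 11, executive 7, language 6) and the 0–30 total onto the 1–10
scale by `clamp(round_half_step(10·raw/max), 1, 10)`.

## Profile dynamics

The sentence builder thresholds each trained domain's training-weight-
weighted mean performance against the controller band and emits one atom
per domain: `dom > current` above the band, `dom < current` below,
`dom = current` inside. Strict atoms make the revision move exactly one
grid step, consistent with the documented 7 → 7.5 example. When several
tasks train one domain with different weights, their performances pool
into the weighted mean before thresholding. Two boundary rules are this
package's additions: a strict atom at the grid ceiling/floor degrades to
equality (the strict form would be unsatisfiable), and untrained domains
are simply omitted (revision leaves them untouched).

Revision enumerates the grid models of the sentence and returns the one
minimizing unit-weighted L1 distance from the current profile. Distance
ties prefer the model whose change concentrates on domains with higher
tiebreak weight (task training weights), implemented as lexicographic
comparison of absolute-change vectors ordered by descending weight;
remaining ties take the lexicographically smallest value vector, so the
operator is a total function. Above the state-space cap,
conjunction-of-single-label-atom sentences (the builder's entire output
fragment) use an equivalent coordinate-wise construction — the sentence
is separable, so per-label nearest admissible values minimize the global
distance; the equivalence is property-tested against the exhaustive
search. An unsatisfiable sentence raises an explicit inconsistency error,
never a silent clamp.

The predicted profile and the intermediary profile fed to the next
session are treated as the same object. Divergence reporting
(predicted vs newly assessed) is descriptive only: signed per-domain
differences, the aggregate weighted distance, and flags above a
configurable threshold (default 0.5, one grid step); no learned cause
attribution.

## Synthetic patients

Each patient holds latent per-domain abilities on 0–100, a Gaussian
noise sd (default 5 percentage points), a logistic slope (default 1.0)
and a learning rate (default 0, i.e. stationary). Performance for a task
at difficulty `d` is `100·logistic(slope·(ability_eff − d))` plus noise,
clipped to [0, 100], where `ability_eff` is the training-weight-weighted
ability mapped to the 1–10 axis. The logistic form is the simplest
mechanism producing the monotone difficulty-performance relationship the
controller assumes, and puts 50% exactly where difficulty matches
ability, making the flow band reachable. Severity presets draw abilities
uniformly: mild [60, 85], moderate [30, 70], severe [10, 40]. All
randomness flows through one explicitly passed generator.

The closed-loop study conditions used in the tests and kept fixed: six
domains with one single-domain task each, moderate-severity patients,
twelve sessions of four plays (plays cycle through the task list across
sessions), start profile 5.5 everywhere on the half-step 1–10 grid,
stationary abilities. Under these conditions the revised profile
converges to roughly `ability/10 − 0.5` (the controller holds difficulty
just below ability, where success stays above 50%), so profile *ranks*
across domains recover ability ranks (mean Spearman ≈ 0.95 over 20
replicates) even though absolute values sit half a step low.

What the simulator does not model: fatigue, day-to-day variability,
strategy shifts, floor/ceiling effects of real instruments, or any
clinical recovery dynamics. Passing closed-loop tests therefore shows
the *engine's* estimator and controller behave as designed against a
well-specified patient model — not that the procedure is clinically
effective, and the pilot-study clinical outcomes are out of scope at
desk scale.

## Files, determinism, degenerate inputs

JSON for structured documents, CSV with a stable column order for
session logs, JSON-lines for the revision audit trail; all formats
round-trip. CLI outputs embed the seed and a configuration hash and
contain no wall-clock timestamps, so identical inputs yield byte-
identical outputs. Exit codes: 0 success (warnings allowed), 2
validation failure, 3 no candidate task or inconsistent sentence.
Degenerate inputs are rejected loudly: empty weight lists, nonpositive
weights, out-of-range raw scores, off-grid profile values, degenerate
score ranges, unknown labels and malformed sentences (with character
position).

## Known limitations

- Expert weights are taken as shipped; no data-driven recalibration.
- The CS percentile backend assumes normal strata; real norms are often
  tabulated nonparametrically.
- The coverage-distance combination across domains (priority-weighted
  sum) and the difficulty-to-parameter linear map are simple defaults,
  not validated against clinical data.
- Revision handles arbitrary sentences only below the enumeration cap;
  above it, only conjunctions of single-label atoms.
- MoCA item ranges in the demo registry are the standard published
  maxima; deployments should supply their own registry.
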