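# Methods

## Scope and model

qcakit implements configurational comparative analysis (crisp- and
fuzzy-set QCA) for the synthesis of a small number of study-level cases.
The object of inference is a set-theoretic *sufficiency* claim: a
configuration of condition memberships X is (quasi-)sufficient for outcome
Y when cases' membership in X is largely contained in their membership in
Y. The analysis does not model sampling error of the underlying effect
sizes; it consumes calibrated memberships and is deliberately insensitive
to effect-size magnitude beyond the calibration levels.

Fuzzy semantics are the standard Zadeh operators: intersection = minimum,
union = maximum, complement = 1 − m. On crisp memberships these reduce to
Boolean logic, and every fuzzy formula below reduces to the corresponding
counting ratio.

## Calibration

Raw odds ratios are calibrated onto four ordered membership levels of the
outcome set through an interval scheme on the logged effect:

| logged OR (natural) | membership | meaning |
|---|---|---|
| > 0.7 | 1.000 | full member ("highly effective") |
| (0.4, 0.7] | 0.666 | more in than out |
| (0, 0.4] | 0.333 | more out than in |
| ≤ 0 | 0.000 | fully out |

Boundary values belong to the lower level (a logged OR of exactly 0.7
yields 0.666). The scheme object exposes the log base (natural by default;
base-10 available for sensitivity work), thresholds and levels, all
validated to be strictly decreasing. Calibration is a monotone step
function of the odds ratio; the unit tests check it against a direct
interval-scan oracle on 1,000 random odds ratios.

Natural log is the default because it reproduces 8 of the 12 published
fuzzy outcomes in the bundled dataset from their raw odds ratios; the four
that differ correspond to cluster-adjusted effect sizes whose adjusted
values were never published, which is why the bundled table stores the
published fuzzy column verbatim rather than re-deriving it.

## Truth table

For the k selected conditions (hard cap 8, i.e. 256 rows, to keep reports
readable) all 2^k corners are enumerated. A case joins the corner it is
more in than out of: bit 1 where membership > 0.5, bit 0 where < 0.5. A
membership of exactly 0.5 is rejected with an instruction to revisit
calibration — the crossover is by definition undecidable.

Raw consistency of a corner's configuration is the fuzzy sufficiency score

    consistency(X → Y) = Σᵢ min(xᵢ, yᵢ) / Σᵢ xᵢ

computed over **all** cases, not only the row's members: a case crisply
assigned elsewhere can still hold partial membership in the configuration
(e.g. a case with quality 0.333 contributes 0.333 to `Intensity*Quality`
while being assigned to the (1,0) corner). This is the only formula that
reproduces the worked example's 0.923 for that row. A frequently quoted
verbal definition of consistency ("cases with the configuration and the
outcome over cases with the outcome") actually describes necessity
(coverage); qcakit implements the sufficiency form throughout and exposes
the necessity form only implicitly as coverage.

Classification precedence per row is: remainder (no cases; consistency
undefined) → contradiction (members on both sides of the 0.5 outcome
crossover) → positive (consistency ≥ cutoff, default 0.75, and case count ≥
frequency cutoff, default 1) → negative. Contradiction deliberately
precedes the cutoff test: a configuration whose own cases disagree about
the outcome should not enter minimisation as a sufficiency claim no matter
how high its aggregate consistency, and the resolution strategies decide
its fate explicitly. Graded but same-side memberships (e.g. 1.0 and 0.666)
are *not* contradictions.

Three resolution strategies are provided: `flag_only` (default — keep the
flag, exclude from minimisation), `recode_zero` (recode as negative,
presenting the row as "unclear"), and `vote_count` (majority of members
above vs below the crossover; ties resolve to negative so that no
sufficiency claim is made without a majority). Strategies that require
re-theorising or re-coding the source studies are analyst actions; the
quality diagnostics (remainder share, class balance, maximum occupancy, a
limited-diversity warning above 50% remainders) surface the triggers for
them but the package does not automate them.

## Minimisation

Positive corners are minimised by Quine–McCluskey: iterative merging of
patterns differing in one position yields the prime implicants; essential
primes are taken first and the residual cover is solved exactly by Petrick
expansion, minimising term count, then total literal count, with a
deterministic lexicographic-label tie-break so identical inputs always
yield identical reports. Exact minimisation is affordable because k is
small in evidence synthesis (the worked example uses k = 2 and 3); the
k ≤ 8 cap keeps the enumeration trivial.

Remainder policy: `conservative` (default) excludes remainders, so the
solution is logically equivalent to the positive-row set on every corner —
the property the test suite verifies by brute-force corner enumeration.
`parsimonious` admits remainders as don't-cares; its solutions are true on
all positives, false on all observed negatives, and never longer than the
conservative solution. Theory-guided ("intermediate") solutions with
directional expectations are not implemented.

## Solution metrics

With sᵢ the solution membership of case i:

* solution coverage = Σ min(sᵢ, yᵢ) / Σ yᵢ
* solution consistency = Σ min(sᵢ, yᵢ) / Σ sᵢ
* per-term raw coverage = Σ min(cᵢ, yᵢ) / Σ yᵢ
* per-term unique coverage = [Σ min(s, y) − Σ min(s₋C, y)] / Σ y, where
  s₋C is the solution with term C removed.

Raw and unique coverage are always reported as separate columns. Published
QCA tables sometimes print a single "unique coverage" column whose values
are in fact raw coverages; keeping both prevents that ambiguity, and the
overlap inequality Σ unique ≤ solution coverage ≤ Σ raw is property-tested.
Coverage and consistency are dual (coverage of Y by X equals consistency of
Y for X), also property-tested.

All metrics and consistencies are kept at full float precision internally
and rounded half-up to three decimals only at the display layer, matching
the membership-level convention (0.666, 0.333).

## Bundled dataset and documented errata

The bundled 12-study breastfeeding table stores the published condition
memberships, raw odds ratios and fuzzy outcomes exactly as printed, with
graded levels held as the literal decimals 0.666/0.333 (not 2/3 and 1/3) —
the downstream arithmetic (e.g. 0.923) reproduces only from the printed
decimals.

Several published analysis figures for this dataset are not derivable from
the published memberships under any standard consistency formula; the
pattern is consistent with some outcome memberships having been revised
between the data table and the analyses. `qcakit.ERRATA` documents each
published value next to the recomputed one (e.g. the three-condition rows
(0,0,1)/(0,0,0)/(1,1,0) recompute to 0.800/0.777/0.666; the two-condition
rows (0,1)/(0,0) to 0.666/0.500; the `Intensity + Quality` solution to
coverage 0.640 and consistency 0.889). qcakit always reports recomputed
values. A visible consequence: from the published memberships the
two-condition model's (0,1) row misses the 0.75 cutoff, so the pipeline's
minimised solution is `Intensity` rather than the published
`Intensity + Quality`; and in the three-condition model the rows (0,0,0)
(positive at 0.777) and (0,0,1) (contradiction-flagged at 0.800) join the
published single passing row. The expression `Intensity + Quality` remains
fully supported as the minimisation of the published passing corners, which
the tests exercise directly.

## Calibration sensitivity

`sensitivity_recalibrate` reruns the entire pipeline with one case's
outcome membership replaced and reports per-row consistency deltas,
solution expressions and metric deltas. The worked sensitivity case moves
the borderline study Pugh (2002) from 0.666 to 0.333. That perturbation
turns the four-study (1,1) row into a genuine 3-vs-1 disagreement, so the
sensitivity run uses `vote_count` resolution — the majority keeps the row
positive, mirroring how a review team would read three full members against
one partial dissent. The result: the solution expression is unchanged while
coverage (0.560 → 0.542) and consistency (0.933 → 0.867) both strictly
decrease — the qualitative message survives, its support weakens. Setting
an outcome to exactly 0.5 is rejected (unclassifiable).

## Synthetic generator

The generator emulates a review-sized study set with a *known* sufficiency
structure: condition bits are drawn Bernoulli(0.5) per case (optionally the
first 2^k cases enumerate every corner, so noise-free recovery is exact by
construction); with probability `fuzziness` a bit is softened to the graded
level on its side of the crossover (1 → 0.666, 0 → 0.333); the outcome is
the case's membership in the planted DNF, flipped to its complement with
probability `consistency_noise`. Defaults are noise-free and crisp — the
cleanest regime for recovery testing; noise 0.3 is used to exercise
contradiction handling. Everything is driven by a single integer seed
through one RNG, so generation is reproducible.

What the generator does *not* emulate: sampling error and standard errors
of effect sizes, correlated conditions, publication bias, or systematically
missing configurations. Passing recovery tests therefore show that the
pipeline's logic is correct, not that real review data will identify the
true structure — real calibrations are uncertain in ways the generator
does not model.

## Numerical and interface choices

* Memberships validated to [0,1]; crisp columns must be exactly 0/1;
  missing values are errors, never imputed — silent imputation would
  corrupt the consistency sums.
* File round-trip is exact at three written decimals; fuzzy values print
  as e.g. `0.666`, never re-rounded to `0.67`.
* Labels use `*` (AND), `+` (OR), `~` (NOT); literal order inside a label
  follows the declared condition order for deterministic output; parsing is
  case-insensitive and whitespace-tolerant.
* Rows sort by descending consistency (ties by descending corner bits),
  remainders last.
* Repeated runs with identical inputs produce byte-identical JSON reports;
  the stage log (counts per stage) goes to standard error.

## Problem sizes

All analyses in the tests and examples are desk-scale: 12 cases and 2–5
conditions for the worked example, k ≤ 5 with a few hundred random tables
for the equivalence properties, and 50 seeded recovery runs at k ≤ 4 — the
full suite runs in a few seconds on one CPU.
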