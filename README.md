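# qcakit

Crisp- and fuzzy-set **qualitative comparative analysis (QCA)** for
evidence synthesis. When a systematic review of complex interventions finds
a handful of heterogeneous trials — too few and too different for
meta-regression — QCA asks a different question: *which combinations of
intervention characteristics are sufficient for a good outcome?* qcakit
implements the full pipeline for review teams working in Python: data-table
validation, calibration of effect sizes into fuzzy set memberships,
truth-table construction with consistency scoring, contradiction handling,
exact Boolean minimisation, and coverage/consistency metrics, plus a small
CLI.

## The method

Each study is a *case* with membership in a set of *conditions* (crisp
{0,1} or fuzzy [0,1]) and in an outcome set Y. Set semantics are the
standard fuzzy ones: AND = min, OR = max, NOT = 1 − m, written
`A*B`, `A + B`, `~A`.

* **Calibration.** A raw odds ratio is mapped to one of four membership
  levels of the outcome set via its natural log: ln OR > 0.7 → 1.0;
  (0.4, 0.7] → 0.666; (0, 0.4] → 0.333; ≤ 0 → 0.0. The 0.5 crossover
  separates "more in" from "more out".
* **Truth table.** For k selected conditions all 2^k configurations are
  enumerated; each case joins the configuration it is more in than out of.
  Sufficiency consistency of configuration X for outcome Y is
  `Σᵢ min(xᵢ, yᵢ) / Σᵢ xᵢ` over **all** cases. Rows are classified
  positive (consistency ≥ 0.75 by default), negative, contradictory
  (members disagree across the 0.5 crossover), or remainder (no cases).
* **Minimisation.** Positive rows are reduced to a minimal DNF by
  Quine–McCluskey with exact (Petrick) cover selection; remainders are
  excluded (conservative) or treated as don't-cares (parsimonious).
* **Solution metrics.** Coverage `Σ min(s, y) / Σ y` (how much of the
  outcome the solution accounts for) and consistency `Σ min(s, y) / Σ s`
  (how reliably the solution delivers the outcome), with per-term raw and
  unique coverage.

## Worked example

The bundled dataset (`qcakit.load_fixture()`) contains 12 controlled trials
of breastfeeding-promotion interventions with community engagement: three
crisp engagement conditions (Empowerment, Design, Lay-led), two graded
conditions identified during synthesis (Quality, Intensity), raw odds
ratios and published fuzzy outcome memberships.

```python
from qcakit import analyse, load_fixture

table = load_fixture()
result = analyse(table, ("Intensity", "Quality"))
print(result.to_text())
```

prints

```
Truth table — cutoff 0.75
 Intensity  Quality  n_cases outcome_class raw_consistency
         1        0        1      positive           1.000
         1        1        4      positive           0.923
         0        1        1      negative           0.666
         0        0        6 contradiction           0.500

Diagnostics:
  rows: 4; remainders: 0 (0%); max occupancy: 6
  positive: 2
  negative: 1
  contradiction: 1
  remainder: 0

Solution (conservative): Intensity
  solution coverage 0.560, solution consistency 0.933
  Intensity: raw coverage 0.560, unique coverage 0.560, consistency 0.933
```

Reading: every study delivering an intense intervention (frequent contact
immediately pre-/post-partum) sits almost entirely inside the set of highly
effective interventions (consistency 0.933 — high intensity is
quasi-sufficient), but intensity accounts for only 56% of the outcome
membership observed (coverage 0.560), so other routes to effectiveness
exist among these trials. The six-study (0,0) row is flagged contradictory
— its members disagree about the outcome — and is therefore kept out of
minimisation.

The bundled dataset also ships `qcakit.ERRATA`, notes on published analysis
figures for this dataset that cannot be recomputed from the published
memberships (e.g. a published solution coverage of 0.714 versus the
recomputed 0.640 for `Intensity + Quality`); qcakit always reports the
recomputed values.

The `examples/` directory walks through each capability: the full worked
analysis (plain and negated outcome), calibration, calibration sensitivity
(one borderline study recalibrated from 0.666 to 0.333 — the solution
survives while coverage drops 0.560 → 0.542 and consistency 0.933 → 0.867),
and recovery of a planted sufficiency structure from synthetic studies.

From a shell:

```sh
qca run --fixture --conditions Intensity,Quality --out results/
qca sensitivity --fixture --conditions Intensity,Quality --strategy vote \
    --case "Pugh (2002)" --set-outcome 0.333
qca generate --k 3 --n 16 --dnf "A + B*~C" --populate-all-corners --out synth.csv
```

Exit status 0 means a solution was found; 3 means no configuration passed
the consistency cutoff.

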