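"""Bundled worked-example dataset and a synthetic study-set generator.

The bundled table holds 12 controlled trials of breastfeeding-promotion
interventions with community engagement: three crisp engagement conditions
(Empowerment, Design, Lay-led), two graded conditions added during the
synthesis (Quality, Intensity — one study has quality 0.333), the raw odds
ratio of each trial, and the published fuzzy membership in the set of
"highly effective interventions".

The published fuzzy outcome column is stored verbatim and is authoritative:
four studies (Long, McInnes, Pugh 2002, Shaw) do not reproduce from their
raw odds ratios under the stated calibration rules because the analysed
effect sizes were adjusted for cluster allocation and the adjusted values
were never published.  :data:`ERRATA` additionally documents the published
truth-table and solution numbers that cannot be recomputed from the
published memberships under any standard consistency formula; this package
reports the recomputed values.

The generator builds study sets with a *known* sufficient-condition
structure (a DNF over the conditions) so that recovery and robustness of
the whole pipeline can be tested at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .data_model import (
    CRISP,
    FUZZY,
    Case,
    ConditionDef,
    DataTable,
    OutcomeDef,
    Schema,
    read_data_table,
)
from .errors import SchemaError
from .set_algebra import Expression, config_membership, parse_label

FIXTURE_SCHEMA = Schema(
    case_id="study",
    conditions=(
        ConditionDef("Empowerment", CRISP, "community members define the health need"),
        ConditionDef("Design", CRISP, "community involvement in intervention design"),
        ConditionDef("Lay-led", CRISP, "delivery led by lay persons / peers"),
        ConditionDef("Quality", FUZZY, "customisable, personal, counselling-based delivery"),
        ConditionDef("Intensity", FUZZY, "frequent contact immediately pre- and post-partum"),
    ),
    outcome=OutcomeDef("highly_effective", calibrated=True),
    raw_effect="raw_or",
)

MODEL1_CONDITIONS = ("Empowerment", "Design", "Lay-led")
MODEL3_CONDITIONS = ("Intensity", "Quality")

#: Published analysis numbers that are NOT reproducible from the published
#: data-table memberships; keys are (analysis, identifier).  The pattern of
#: discrepancies is consistent with several outcome memberships (Chapman,
#: Long, McInnes, Shaw, Pugh 2002) having been revised between the data
#: table and the downstream analyses.  qcakit reports the recomputed values.
ERRATA: dict[tuple[str, object], dict[str, float]] = {
    ("model1_consistency", (0, 0, 1)): {"published": 0.666, "recomputed": 0.800},
    ("model1_consistency", (0, 0, 0)): {"published": 0.666, "recomputed": 0.777},
    ("model1_consistency", (1, 1, 0)): {"published": 0.333, "recomputed": 0.666},
    ("model3_consistency", (0, 1)): {"published": 0.750, "recomputed": 0.666},
    ("model3_consistency", (0, 0)): {"published": 0.389, "recomputed": 0.500},
    ("solution", "coverage"): {"published": 0.714, "recomputed": 0.640},
    ("solution", "consistency"): {"published": 0.833, "recomputed": 0.889},
    ("solution", "intensity_raw_coverage"): {"published": 0.667, "recomputed": 0.560},
}


def load_fixture() -> DataTable:
    """The 12-study breastfeeding worked-example data table."""
    path = resources.files("qcakit.data").joinpath("breastfeeding.csv")
    with resources.as_file(path) as fname:
        return read_data_table(fname, FIXTURE_SCHEMA)


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for a synthetic study set with known sufficiency structure.

    ``true_dnf`` (a label string or Expression over the generated condition
    names) defines which configurations are sufficient for the outcome.
    Condition memberships are drawn Bernoulli(0.5) at the corners; with
    probability ``fuzziness`` a membership is softened to the graded level
    on its side of the crossover (1 -> 0.666, 0 -> 0.333).  The outcome is
    the case's membership in ``true_dnf``, flipped to its fuzzy complement
    with probability ``consistency_noise``.  With ``populate_all_corners``
    the first 2^k cases enumerate every corner so that noise-free recovery
    is exact by construction.
    """

    k: int
    n: int
    true_dnf: str | Expression
    consistency_noise: float = 0.0
    fuzziness: float = 0.0
    seed: int = 0
    populate_all_corners: bool = False
    condition_names: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.k < 1:
            raise SchemaError("k must be at least 1")
        if self.n < 1:
            raise SchemaError("n must be at least 1")
        if not 0.0 <= self.consistency_noise < 1.0:
            raise SchemaError("consistency_noise must lie in [0, 1)")
        if not 0.0 <= self.fuzziness <= 1.0:
            raise SchemaError("fuzziness must lie in [0, 1]")
        if self.condition_names is not None and len(self.condition_names) != self.k:
            raise SchemaError("condition_names must have length k")


def _default_names(k: int) -> tuple[str, ...]:
    if k <= 26:
        return tuple(chr(ord("A") + i) for i in range(k))
    return tuple(f"C{i + 1}" for i in range(k))


def generate(spec: GeneratorSpec) -> DataTable:
    """Deterministic (seeded) synthetic study set per :class:`GeneratorSpec`."""
    names = spec.condition_names or _default_names(spec.k)
    kind = FUZZY if spec.fuzziness > 0 else CRISP
    conditions = tuple(ConditionDef(name, kind) for name in names)
    dnf = spec.true_dnf if isinstance(spec.true_dnf, Expression) else parse_label(spec.true_dnf, names)
    for term in dnf.terms:
        for lit in term.literals:
            if lit.condition.casefold() not in {n.casefold() for n in names}:
                raise SchemaError(f"true_dnf references undeclared condition {lit.condition!r}")

    rng = np.random.default_rng(spec.seed)
    cases = []
    for i in range(spec.n):
        if spec.populate_all_corners and i < 2**spec.k:
            bits = [(i >> (spec.k - 1 - j)) & 1 for j in range(spec.k)]
        else:
            bits = rng.integers(0, 2, size=spec.k).tolist()
        memberships = {}
        for name, bit in zip(names, bits):
            value = float(bit)
            if spec.fuzziness > 0 and rng.random() < spec.fuzziness:
                value = 0.666 if bit else 0.333
            memberships[name] = value
        case = Case(case_id=f"case{i + 1:03d}", memberships=memberships, outcome=0.0)
        outcome = max(config_membership(case, term) for term in dnf.terms)
        if spec.consistency_noise > 0 and rng.random() < spec.consistency_noise:
            outcome = 1.0 - outcome
        cases.append(Case(case_id=case.case_id, memberships=memberships, outcome=outcome))
    return DataTable(conditions=conditions, outcome=OutcomeDef("outcome"), cases=tuple(cases))
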