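"""Case-by-condition data tables for configurational comparative analysis.

A :class:`DataTable` holds one row per study ("case"), one column per
condition (crisp {0,1} or fuzzy [0,1] membership) and a single outcome
membership, optionally alongside the raw effect size (odds ratio) it was
calibrated from.  Tables are read from and written to delimited text with a
declared :class:`Schema`; validation is strict — missing memberships, values
outside [0,1] and non-crisp values in crisp columns are input errors, never
silently imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataValidationError, SchemaError
from .rounding import fmt3

CRISP = "crisp"
FUZZY = "fuzzy"


@dataclass(frozen=True)
class ConditionDef:
    """A named condition (explanatory set) with crisp or fuzzy membership."""

    name: str
    kind: str = CRISP
    description: str | None = None

    def __post_init__(self):
        if not self.name or not self.name.strip():
            raise SchemaError("condition name must be non-empty")
        if self.kind not in (CRISP, FUZZY):
            raise SchemaError(f"condition {self.name!r}: kind must be 'crisp' or 'fuzzy', got {self.kind!r}")


@dataclass(frozen=True)
class OutcomeDef:
    """The outcome set; ``calibrated`` is False when the column holds raw effect sizes."""

    name: str
    calibrated: bool = True

    def __post_init__(self):
        if not self.name or not self.name.strip():
            raise SchemaError("outcome name must be non-empty")


@dataclass(frozen=True)
class Case:
    """One study: named condition memberships, an outcome membership, and
    optionally the raw effect size (odds-ratio scale) behind the outcome."""

    case_id: str
    memberships: Mapping[str, float]
    outcome: float
    raw_effect: float | None = None

    def membership(self, condition: str) -> float:
        """Membership of this case in ``condition`` (case-insensitive lookup)."""
        if condition in self.memberships:
            return self.memberships[condition]
        folded = condition.casefold()
        for name, value in self.memberships.items():
            if name.casefold() == folded:
                return value
        raise KeyError(f"case {self.case_id!r} has no membership for condition {condition!r}")


@dataclass(frozen=True)
class DataTable:
    """The full case set plus condition/outcome definitions."""

    conditions: tuple[ConditionDef, ...]
    outcome: OutcomeDef
    cases: tuple[Case, ...]

    def __post_init__(self):
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "cases", tuple(self.cases))
        if not self.conditions:
            raise SchemaError("a data table needs at least one condition")
        if not self.cases:
            raise DataValidationError("a data table needs at least one case")
        folded = [c.name.casefold() for c in self.conditions]
        if len(set(folded)) != len(folded):
            raise SchemaError("condition names must be unique (case-insensitive)")
        seen_ids: set[str] = set()
        for case in self.cases:
            if case.case_id in seen_ids:
                raise DataValidationError(f"duplicate case_id {case.case_id!r}")
            seen_ids.add(case.case_id)
            for cond in self.conditions:
                try:
                    value = case.membership(cond.name)
                except KeyError as exc:
                    raise DataValidationError(str(exc)) from exc
                _check_membership(value, case.case_id, cond.name, crisp=(cond.kind == CRISP))
            _check_membership(case.outcome, case.case_id, self.outcome.name, crisp=False)
            if case.raw_effect is not None and case.raw_effect <= 0:
                raise DataValidationError(
                    f"case {case.case_id!r}: raw effect size must be positive, got {case.raw_effect}"
                )

    @property
    def condition_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.conditions)

    def condition(self, name: str) -> ConditionDef:
        folded = name.casefold()
        for cond in self.conditions:
            if cond.name.casefold() == folded:
                return cond
        raise SchemaError(f"unknown condition {name!r}; declared: {', '.join(self.condition_names)}")

    def case(self, case_id: str) -> Case:
        for case in self.cases:
            if case.case_id == case_id:
                return case
        raise DataValidationError(f"unknown case_id {case_id!r}")

    def with_outcome(self, case_id: str, new_outcome: float) -> "DataTable":
        """A copy of the table with one case's outcome membership replaced."""
        self.case(case_id)  # raise early on unknown id
        new_cases = tuple(
            replace(c, outcome=float(new_outcome)) if c.case_id == case_id else c for c in self.cases
        )
        return DataTable(self.conditions, self.outcome, new_cases)

    def outcome_values(self, negated: bool = False) -> list[float]:
        return [1.0 - c.outcome if negated else c.outcome for c in self.cases]


def _check_membership(value: float, case_id: str, column: str, crisp: bool) -> None:
    if not isinstance(value, (int, float)) or isinstance(value, bool) or math.isnan(value):
        raise DataValidationError(f"case {case_id!r}, column {column!r}: non-numeric membership {value!r}")
    if not 0.0 <= value <= 1.0:
        raise DataValidationError(
            f"case {case_id!r}, column {column!r}: membership {value} outside [0, 1]"
        )
    if crisp and value not in (0.0, 1.0):
        raise DataValidationError(
            f"case {case_id!r}, column {column!r}: crisp condition requires 0 or 1, got {value}"
        )


@dataclass(frozen=True)
class Schema:
    """Column declarations for a delimited data file.

    ``case_id`` names the study-label column; condition columns are named by
    their :class:`ConditionDef`; the outcome column is named by the
    :class:`OutcomeDef` and may hold either a calibrated membership or (when
    ``outcome.calibrated`` is False) a raw odds ratio to be calibrated on
    read.  ``raw_effect`` optionally names a column of raw odds ratios kept
    alongside a pre-calibrated outcome.
    """

    case_id: str
    conditions: tuple[ConditionDef, ...]
    outcome: OutcomeDef
    raw_effect: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if not self.conditions:
            raise SchemaError("schema declares no conditions")

    @classmethod
    def from_dict(cls, doc: Mapping) -> "Schema":
        try:
            conds = []
            raw_conditions = doc["conditions"]
            if isinstance(raw_conditions, Mapping):
                items: Iterable = ({"name": k, "kind": v} for k, v in raw_conditions.items())
            else:
                items = raw_conditions
            for item in items:
                conds.append(
                    ConditionDef(
                        name=item["name"],
                        kind=item.get("kind", CRISP),
                        description=item.get("description"),
                    )
                )
            out = doc["outcome"]
            outcome = OutcomeDef(name=out["name"], calibrated=bool(out.get("calibrated", True)))
            return cls(
                case_id=doc.get("case_id", "case_id"),
                conditions=tuple(conds),
                outcome=outcome,
                raw_effect=doc.get("raw_effect"),
            )
        except KeyError as exc:
            raise SchemaError(f"schema document missing key: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Schema":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, Mapping):
            raise SchemaError(f"schema file {path} is not a mapping document")
        return cls.from_dict(doc)


def _infer_sep(path: str | Path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    suffix = Path(path).suffix.lower()
    return "\t" if suffix in (".tsv", ".tab") else ","


def _resolve_column(df: pd.DataFrame, name: str) -> str:
    if name in df.columns:
        return name
    folded = name.casefold()
    for col in df.columns:
        if str(col).casefold() == folded:
            return str(col)
    raise SchemaError(f"declared column {name!r} not found in file (columns: {', '.join(map(str, df.columns))})")


def _parse_cell(raw, case_id: str, column: str) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
        raise DataValidationError(f"case {case_id!r}, column {column!r}: missing value")
    try:
        return float(str(raw).strip())
    except ValueError as exc:
        raise DataValidationError(
            f"case {case_id!r}, column {column!r}: cannot parse {raw!r} as a number"
        ) from exc


def read_data_table(
    path: str | Path,
    schema: Schema,
    *,
    delimiter: str | None = None,
    scheme=None,
) -> DataTable:
    """Read and validate a delimited data table.

    The dialect is inferred from the extension (``.tsv``/``.tab`` → tab,
    otherwise comma) unless ``delimiter`` overrides it.  When the schema's
    outcome is declared uncalibrated, the outcome column is treated as a raw
    odds ratio and calibrated with ``scheme`` (default scheme if None).
    """
    df = pd.read_csv(path, sep=_infer_sep(path, delimiter), dtype=str)
    id_col = _resolve_column(df, schema.case_id)
    cond_cols = {c.name: _resolve_column(df, c.name) for c in schema.conditions}
    out_col = _resolve_column(df, schema.outcome.name)
    raw_col = _resolve_column(df, schema.raw_effect) if schema.raw_effect else None

    if not schema.outcome.calibrated:
        from .calibration import DEFAULT_SCHEME, calibrate_effect

        scheme = scheme or DEFAULT_SCHEME

    cases = []
    for _, row in df.iterrows():
        case_id = str(row[id_col])
        memberships = {
            cond.name: _parse_cell(row[cond_cols[cond.name]], case_id, cond.name)
            for cond in schema.conditions
        }
        raw_effect = None
        if raw_col is not None:
            raw_value = row[raw_col]
            if raw_value is not None and str(raw_value).strip() not in ("", "nan"):
                raw_effect = _parse_cell(raw_value, case_id, raw_col)
        out_raw = _parse_cell(row[out_col], case_id, out_col)
        if schema.outcome.calibrated:
            outcome = out_raw
        else:
            from .calibration import calibrate_effect

            raw_effect = out_raw
            outcome = calibrate_effect(out_raw, scheme)
        cases.append(Case(case_id=case_id, memberships=memberships, outcome=outcome, raw_effect=raw_effect))

    outcome_def = OutcomeDef(schema.outcome.name, calibrated=True)
    return DataTable(conditions=schema.conditions, outcome=outcome_def, cases=tuple(cases))


def write_data_table(table: DataTable, path: str | Path, *, delimiter: str | None = None) -> None:
    """Write a validated table as delimited text.

    Layout mirrors the analysis convention: case id first, conditions in
    declared order, raw effect (when any case carries one), outcome last.
    Crisp memberships print as integers; fuzzy memberships and the outcome
    print with exactly three fractional digits, so ``read(write(t))`` is the
    identity at that precision.
    """
    if not isinstance(table, DataTable):
        raise DataValidationError("write_data_table expects a DataTable")
    sep = _infer_sep(path, delimiter)
    has_raw = any(c.raw_effect is not None for c in table.cases)
    columns = ["case_id", *table.condition_names]
    if has_raw:
        columns.append("raw_effect")
    columns.append(table.outcome.name)

    rows = []
    for case in table.cases:
        row = [case.case_id]
        for cond in table.conditions:
            value = case.membership(cond.name)
            row.append(str(int(value)) if cond.kind == CRISP else fmt3(value))
        if has_raw:
            row.append("" if case.raw_effect is None else fmt3(case.raw_effect))
        row.append(fmt3(case.outcome))
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep=sep, index=False)


def table_schema(table: DataTable, *, case_id: str = "case_id", raw_effect: str | None = None) -> Schema:
    """Schema matching what :func:`write_data_table` produces for ``table``."""
    has_raw = any(c.raw_effect is not None for c in table.cases)
    return Schema(
        case_id=case_id,
        conditions=table.conditions,
        outcome=OutcomeDef(table.outcome.name, calibrated=True),
        raw_effect=raw_effect if raw_effect is not None else ("raw_effect" if has_raw else None),
    )
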