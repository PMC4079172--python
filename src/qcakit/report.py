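"""End-to-end analysis pipeline and reproducible reports.

:func:`analyse` runs the stages on an in-memory table: truth-table
construction, contradiction resolution, diagnostics, Boolean minimisation
and solution metrics.  :func:`run_analysis` wraps it with file I/O — data
echo, truth table, plain-text report and a versioned machine-readable JSON
bundle whose bytes depend only on the inputs and settings (the run log goes
to standard error, so repeated runs produce identical JSON).

:func:`sensitivity_recalibrate` reruns the full analysis with one case's
outcome membership replaced and reports the deltas — the calibration
sensitivity check described in the methods note.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from .data_model import DataTable, Schema, read_data_table, write_data_table
from .errors import NoSolutionError
from .metrics import SolutionMetrics, component_coverages
from .minimise import CONSERVATIVE, Solution, minimise
from .rounding import fmt3, round3
from .set_algebra import format_expression
from .truth_table import (
    FLAG_ONLY,
    OutcomeClass,
    TruthTable,
    TruthTableDiagnostics,
    build_truth_table,
    quality_report,
    resolve_contradictions,
    write_truth_table,
)

REPORT_SCHEMA_VERSION = 1

log = logging.getLogger("qcakit")
if not log.handlers:
    _handler = logging.StreamHandler(sys.stderr)
    _handler.setFormatter(logging.Formatter("qca [%(stage)s] %(message)s"))
    log.addHandler(_handler)
    log.setLevel(logging.INFO)


def _stage(stage: str, message: str) -> None:
    log.info(message, extra={"stage": stage})


@dataclass(frozen=True)
class RunConfig:
    """Settings for one analysis run (CLI and config-file surface)."""

    data: str | Path | None = None
    schema: Schema | None = None
    conditions: tuple[str, ...] | None = None
    negate_outcome: bool = False
    calibration_scheme: object | None = None  # used when the outcome column is raw
    consistency_cutoff: float = 0.75
    frequency_cutoff: int = 1
    strategy: str = FLAG_ONLY
    policy: str = CONSERVATIVE
    out_dir: str | Path | None = None

    def __post_init__(self):
        if not 0.0 < self.consistency_cutoff <= 1.0:
            raise ValueError("consistency cutoff must lie in (0, 1]")


@dataclass(frozen=True)
class AnalysisResult:
    table: DataTable
    truth_table: TruthTable
    diagnostics: TruthTableDiagnostics
    solution: Solution | None
    metrics: SolutionMetrics | None
    settings: dict

    @property
    def solution_label(self) -> str | None:
        if self.solution is None:
            return None
        return format_expression(self.solution.expression, self.truth_table.conditions)

    def to_json_dict(self) -> dict:
        tt = self.truth_table
        doc = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "settings": self.settings,
            "truth_table": {
                "conditions": list(tt.conditions),
                "consistency_cutoff": tt.consistency_cutoff,
                "frequency_cutoff": tt.frequency_cutoff,
                "outcome_negated": tt.outcome_negated,
                "rows": [
                    {
                        "corner": list(r.corner),
                        "cases": list(r.case_ids),
                        "n_cases": r.n_cases,
                        "raw_consistency": None if r.raw_consistency is None else round3(r.raw_consistency),
                        "outcome_class": r.outcome_class.value,
                        "note": r.note,
                    }
                    for r in tt.rows
                ],
            },
            "diagnostics": asdict(self.diagnostics),
            "contradictions": [
                {"corner": list(r.corner), "note": r.note}
                for r in tt.rows
                if r.outcome_class is OutcomeClass.CONTRADICTION
            ],
            "solution": None,
        }
        doc["diagnostics"]["warnings"] = list(self.diagnostics.warnings)
        if self.solution is not None and self.metrics is not None:
            doc["solution"] = {
                "expression": self.solution_label,
                "policy": self.solution.policy,
                "dont_cares": sorted(list(c) for c in self.solution.dont_cares),
                "coverage": round3(self.metrics.solution_coverage),
                "consistency": round3(self.metrics.solution_consistency),
                "components": [
                    {
                        "label": c.label,
                        "raw_coverage": round3(c.raw_coverage),
                        "unique_coverage": round3(c.unique_coverage),
                        "consistency": None if c.consistency is None else round3(c.consistency),
                    }
                    for c in self.metrics.components
                ],
            }
        return doc

    def to_text(self) -> str:
        lines = [
            "Truth table"
            + (" (negated outcome)" if self.truth_table.outcome_negated else "")
            + f" — cutoff {self.truth_table.consistency_cutoff}",
            self.truth_table.to_frame().to_string(index=False),
            "",
            "Diagnostics:",
        ]
        diag = self.diagnostics
        lines.append(
            f"  rows: {diag.n_rows}; remainders: {diag.n_remainders} "
            f"({diag.remainder_fraction:.0%}); max occupancy: {diag.max_row_occupancy}"
        )
        for name, count in diag.class_counts.items():
            lines.append(f"  {name}: {count}")
        for warning in diag.warnings:
            lines.append(f"  warning: {warning}")
        lines.append("")
        if self.solution is None:
            lines.append("Solution: none — no configuration passed the consistency cutoff")
        else:
            lines.append(f"Solution ({self.solution.policy}): {self.solution_label}")
            lines.append(
                f"  solution coverage {fmt3(self.metrics.solution_coverage)}, "
                f"solution consistency {fmt3(self.metrics.solution_consistency)}"
            )
            for c in self.metrics.components:
                lines.append(
                    f"  {c.label}: raw coverage {fmt3(c.raw_coverage)}, "
                    f"unique coverage {fmt3(c.unique_coverage)}, "
                    f"consistency {'n/a' if c.consistency is None else fmt3(c.consistency)}"
                )
        return "\n".join(lines) + "\n"


def analyse(
    table: DataTable,
    conditions: Sequence[str] | None = None,
    *,
    negate_outcome: bool = False,
    consistency_cutoff: float = 0.75,
    frequency_cutoff: int = 1,
    strategy: str = FLAG_ONLY,
    policy: str = CONSERVATIVE,
) -> AnalysisResult:
    """Run truth table -> contradiction resolution -> minimisation -> metrics.

    Returns an :class:`AnalysisResult` whose ``solution`` and ``metrics``
    are None when no row passes the consistency cutoff.
    """
    settings = {
        "conditions": list(conditions) if conditions else list(table.condition_names),
        "negate_outcome": negate_outcome,
        "consistency_cutoff": consistency_cutoff,
        "frequency_cutoff": frequency_cutoff,
        "strategy": strategy,
        "policy": policy,
    }
    _stage("data", f"{len(table.cases)} cases, {len(table.conditions)} conditions")
    tt = build_truth_table(
        table,
        conditions,
        consistency_cutoff=consistency_cutoff,
        frequency_cutoff=frequency_cutoff,
        outcome_negated=negate_outcome,
    )
    _stage("truth-table", f"{len(tt.rows)} rows built over {', '.join(tt.conditions)}")
    tt = resolve_contradictions(tt, strategy)
    diagnostics = quality_report(tt)
    _stage(
        "truth-table",
        f"{diagnostics.class_counts['positive']} positive, "
        f"{diagnostics.class_counts['contradiction']} contradictory, "
        f"{diagnostics.n_remainders} remainder rows",
    )
    solution = None
    metrics = None
    try:
        solution = minimise(
            tt.positive_corners, tt.remainder_corners, policy=policy, conditions=tt.conditions
        )
        metrics = component_coverages(table, solution, outcome_negated=negate_outcome)
        _stage("minimise", f"solution: {format_expression(solution.expression, tt.conditions)}")
    except NoSolutionError:
        _stage("minimise", "no configuration passed the consistency cutoff")
    return AnalysisResult(
        table=table,
        truth_table=tt,
        diagnostics=diagnostics,
        solution=solution,
        metrics=metrics,
        settings=settings,
    )


def _load_table(config: RunConfig) -> DataTable:
    if config.data is None or config.schema is None:
        raise ValueError("RunConfig needs both a data path and a schema")
    return read_data_table(config.data, config.schema, scheme=config.calibration_scheme)


def run_analysis(config: RunConfig, table: DataTable | None = None) -> AnalysisResult:
    """Full pipeline with file outputs under ``config.out_dir`` (when set):
    ``data_table.csv``, ``truth_table.csv``, ``report.txt``, ``report.json``."""
    if table is None:
        table = _load_table(config)
    result = analyse(
        table,
        config.conditions,
        negate_outcome=config.negate_outcome,
        consistency_cutoff=config.consistency_cutoff,
        frequency_cutoff=config.frequency_cutoff,
        strategy=config.strategy,
        policy=config.policy,
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_data_table(result.table, out / "data_table.csv")
        write_truth_table(result.truth_table, out / "truth_table.csv")
        (out / "report.txt").write_text(result.to_text())
        (out / "report.json").write_text(
            json.dumps(result.to_json_dict(), indent=2, sort_keys=True) + "\n"
        )
        _stage("report", f"wrote report bundle to {out}")
    return result


@dataclass(frozen=True)
class SensitivityResult:
    case_id: str
    original_outcome: float
    alternative_outcome: float
    base: AnalysisResult
    altered: AnalysisResult

    @property
    def solution_changed(self) -> bool:
        return self.base.solution_label != self.altered.solution_label

    def consistency_deltas(self) -> dict[tuple[int, ...], float | None]:
        """Per-corner change in raw consistency (altered - base)."""
        deltas: dict[tuple[int, ...], float | None] = {}
        for row in self.base.truth_table.rows:
            alt = self.altered.truth_table.row(row.corner)
            if row.raw_consistency is None or alt.raw_consistency is None:
                deltas[row.corner] = None
            else:
                deltas[row.corner] = alt.raw_consistency - row.raw_consistency
        return deltas

    def to_json_dict(self) -> dict:
        def metric_delta(attr):
            if self.base.metrics is None or self.altered.metrics is None:
                return None
            return round3(getattr(self.altered.metrics, attr) - getattr(self.base.metrics, attr))

        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "case_id": self.case_id,
            "original_outcome": round3(self.original_outcome),
            "alternative_outcome": round3(self.alternative_outcome),
            "base_solution": self.base.solution_label,
            "altered_solution": self.altered.solution_label,
            "solution_changed": self.solution_changed,
            "coverage_delta": metric_delta("solution_coverage"),
            "consistency_delta": metric_delta("solution_consistency"),
            "row_consistency_deltas": [
                {"corner": list(corner), "delta": None if d is None else round3(d)}
                for corner, d in self.consistency_deltas().items()
            ],
            "base": self.base.to_json_dict(),
            "altered": self.altered.to_json_dict(),
        }


def sensitivity_recalibrate(
    config: RunConfig,
    case_id: str,
    alternative_outcome: float,
    table: DataTable | None = None,
) -> SensitivityResult:
    """Rerun the full analysis with one case's outcome membership replaced
    and report deltas in row consistencies, solution and solution metrics."""
    if table is None:
        table = _load_table(config)
    original = table.case(case_id).outcome
    if alternative_outcome == 0.5:
        from .errors import MembershipAssignmentError

        raise MembershipAssignmentError(
            f"[sensitivity] case {case_id!r}: an outcome of exactly 0.5 is precisely neither in "
            "nor out of the outcome set and cannot be classified; choose a side of the crossover"
        )
    altered_table = table.with_outcome(case_id, alternative_outcome)
    _stage("sensitivity", f"{case_id}: outcome {round3(original)} -> {round3(alternative_outcome)}")
    base = run_analysis(config, table=table)
    altered = run_analysis(
        RunConfig(
            data=config.data,
            schema=config.schema,
            conditions=config.conditions,
            negate_outcome=config.negate_outcome,
            calibration_scheme=config.calibration_scheme,
            consistency_cutoff=config.consistency_cutoff,
            frequency_cutoff=config.frequency_cutoff,
            strategy=config.strategy,
            policy=config.policy,
            out_dir=None,
        ),
        table=altered_table,
    )
    result = SensitivityResult(
        case_id=case_id,
        original_outcome=original,
        alternative_outcome=alternative_outcome,
        base=base,
        altered=altered,
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "sensitivity.json").write_text(
            json.dumps(result.to_json_dict(), indent=2, sort_keys=True) + "\n"
        )
    return result
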