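import numpy as np
import pytest

from qcakit import (
    Case,
    ConditionDef,
    DataTable,
    MembershipAssignmentError,
    OutcomeClass,
    OutcomeDef,
    assign_row,
    build_truth_table,
    detect_contradiction,
    parse_label,
    quality_report,
    raw_consistency,
    resolve_contradictions,
)
from qcakit.fixtures import GeneratorSpec, generate
from qcakit.rounding import round3
from qcakit.truth_table import TruthTableRow, corner_configuration

CONDS = ("Empowerment", "Design", "Lay-led", "Quality", "Intensity")


def _config(label):
    return parse_label(label, CONDS).terms[0]


class TestAssignment:
    def test_fuzzy_case_joins_nearest_corner(self, breastfeeding):
        caulfield = breastfeeding.case("Caulfield (1998)")
        assert assign_row(caulfield, ("Intensity", "Quality")) == (1, 0)

    def test_crisp_case_is_its_own_corner(self, breastfeeding):
        mcinnes = breastfeeding.case("McInnes (1998)")
        assert assign_row(mcinnes, ("Empowerment", "Design", "Lay-led")) == (1, 1, 1)

    def test_crossover_membership_is_undecidable(self):
        case = Case("s1", {"A": 0.5}, 1.0)
        with pytest.raises(MembershipAssignmentError, match="s1.*A"):
            assign_row(case, ("A",))


class TestRawConsistency:
    @pytest.mark.parametrize(
        "label,negated,expected",
        [
            ("Intensity*Quality", False, 0.923),        # (1+0.333+1+0.666+1)/(1+0.333+1+1+1)
            ("~Empowerment*Design*Lay-led", False, 1.000),
            ("Empowerment*Design*Lay-led", False, 0.333),
            ("Empowerment*Design*Lay-led", True, 0.667),
            ("~Empowerment*~Design*Lay-led", False, 0.800),  # (1+1+1+0.333+0.666)/5
        ],
    )
    def test_fixture_consistencies(self, breastfeeding, label, negated, expected):
        value = raw_consistency(breastfeeding, _config(label), outcome_negated=negated)
        assert round3(value) == expected

    def test_plain_plus_negated_is_one_for_crisp_configurations(self, breastfeeding):
        # when every case's configuration membership is 0 or 1,
        # sum(min(x,y)) + sum(min(x,1-y)) = sum(x)
        tt = build_truth_table(breastfeeding, ("Empowerment", "Design", "Lay-led"))
        for row in tt.rows:
            if row.raw_consistency is None:
                continue
            config = corner_configuration(row.corner, tt.conditions)
            plain = raw_consistency(breastfeeding, config)
            negated = raw_consistency(breastfeeding, config, outcome_negated=True)
            assert plain + negated == pytest.approx(1.0)

    def test_crisp_tables_match_the_counting_oracle(self):
        """With crisp conditions and a crisp outcome, fuzzy consistency must
        equal (members showing the outcome) / (members)."""
        for seed in range(6):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(2, 5))
            n = int(rng.integers(5, 31))
            table = generate(
                GeneratorSpec(k=k, n=n, true_dnf="A", consistency_noise=0.4, seed=seed)
            )
            tt = build_truth_table(table)
            for row in tt.rows:
                if not row.case_ids:
                    continue
                members = [table.case(cid) for cid in row.case_ids]
                counted = sum(1 for m in members if m.outcome == 1.0) / len(members)
                assert row.raw_consistency == pytest.approx(counted)


class TestBuild:
    def test_model3_row_occupancy(self, breastfeeding, model3):
        tt = build_truth_table(breastfeeding, model3)
        counts = {r.corner: r.n_cases for r in tt.rows}
        assert counts == {(1, 0): 1, (1, 1): 4, (0, 1): 1, (0, 0): 6}

    def test_model1_rows_and_remainders(self, breastfeeding, model1):
        tt = build_truth_table(breastfeeding, model1)
        assert len(tt.rows) == 8
        assert set(tt.remainder_corners) == {(1, 0, 0), (1, 0, 1)}
        assert tt.row((0, 0, 1)).n_cases == 5

    def test_every_case_in_exactly_one_row(self, breastfeeding, model1):
        tt = build_truth_table(breastfeeding, model1)
        all_ids = [cid for row in tt.rows for cid in row.case_ids]
        assert sorted(all_ids) == sorted(c.case_id for c in breastfeeding.cases)

    def test_rows_sorted_by_descending_consistency_remainders_last(self, breastfeeding, model1):
        tt = build_truth_table(breastfeeding, model1)
        occupied = [r for r in tt.rows if r.raw_consistency is not None]
        values = [r.raw_consistency for r in occupied]
        assert values == sorted(values, reverse=True)
        assert all(r.raw_consistency is None for r in tt.rows[len(occupied):])

    def test_single_crisp_case_yields_one_remainder(self):
        table = DataTable(
            conditions=(ConditionDef("A"),),
            outcome=OutcomeDef("y"),
            cases=(Case("s1", {"A": 1.0}, 1.0),),
        )
        tt = build_truth_table(table)
        assert len(tt.rows) == 2
        assert tt.remainder_corners == ((0,),)
        assert tt.row((1,)).outcome_class is OutcomeClass.POSITIVE

    def test_mixed_row_is_flagged_not_classified_positive(self, breastfeeding, model1):
        # (0,0,1) clears the cutoff at 0.800 but its five members disagree
        # (Long 0.333 against three full members), so it is a contradiction
        tt = build_truth_table(breastfeeding, model1)
        row = tt.row((0, 0, 1))
        assert row.outcome_class is OutcomeClass.CONTRADICTION
        assert round3(row.raw_consistency) == 0.800


class TestContradictions:
    def test_consistent_high_membership_row_is_not_contradictory(self, breastfeeding, model3):
        tt = build_truth_table(breastfeeding, model3)
        contradictory, note = detect_contradiction(tt.row((1, 1)))
        assert not contradictory
        assert "Pugh (2002)=0.666" in note

    def test_single_member_fuzzy_row_is_not_contradictory(self, breastfeeding, model3):
        tt = build_truth_table(breastfeeding, model3)
        assert not detect_contradiction(tt.row((0, 1)))[0]

    def test_disagreeing_members_are_contradictory(self):
        row = TruthTableRow((1,), ("a", "b"), (1.0, 0.0), 0.5, OutcomeClass.NEGATIVE)
        assert detect_contradiction(row)[0]

    def test_recode_zero_makes_contradictions_negative(self, breastfeeding, model1):
        tt = resolve_contradictions(build_truth_table(breastfeeding, model1), "recode_zero")
        assert tt.row((0, 0, 1)).outcome_class is OutcomeClass.NEGATIVE

    def test_vote_count_majority_and_tie(self):
        majority = TruthTableRow((1,), ("a", "b", "c"), (1.0, 1.0, 0.0), 0.7, OutcomeClass.CONTRADICTION)
        tie = TruthTableRow((0,), ("d", "e"), (1.0, 0.0), 0.5, OutcomeClass.CONTRADICTION)
        from qcakit.truth_table import TruthTable

        tt = TruthTable(("A",), (majority, tie), 0.75, 1, False)
        resolved = resolve_contradictions(tt, "vote_count")
        assert resolved.row((1,)).outcome_class is OutcomeClass.POSITIVE
        assert resolved.row((0,)).outcome_class is OutcomeClass.NEGATIVE

    def test_flag_only_leaves_classes(self, breastfeeding, model1):
        tt = build_truth_table(breastfeeding, model1)
        assert resolve_contradictions(tt, "flag_only") is tt


class TestDiagnostics:
    def test_model1_spread(self, breastfeeding, model1):
        diag = quality_report(build_truth_table(breastfeeding, model1))
        assert diag.n_remainders == 2
        assert diag.n_rows == 8
        assert not diag.limited_diversity
        assert diag.max_row_occupancy == 5

    def test_negated_model_warns_about_single_passing_row(self, breastfeeding, model1):
        tt = build_truth_table(breastfeeding, model1, outcome_negated=True)
        diag = quality_report(tt)
        assert any("only one configuration" in w for w in diag.warnings)

    def test_model3_has_no_remainders(self, breastfeeding, model3):
        diag = quality_report(build_truth_table(breastfeeding, model3))
        assert diag.n_remainders == 0

    def test_fully_populated_single_condition_table_is_clean(self):
        table = DataTable(
            conditions=(ConditionDef("A"),),
            outcome=OutcomeDef("y"),
            cases=(
                Case("s1", {"A": 1.0}, 1.0),
                Case("s2", {"A": 1.0}, 1.0),
                Case("s3", {"A": 0.0}, 0.0),
            ),
        )
        diag = quality_report(build_truth_table(table))
        assert diag.n_remainders == 0
        assert diag.warnings == ()

    def test_limited_diversity_warning(self):
        table = DataTable(
            conditions=tuple(ConditionDef(n) for n in "ABCD"),
            outcome=OutcomeDef("y"),
            cases=(Case("s1", {n: 1.0 for n in "ABCD"}, 1.0),),
        )
        diag = quality_report(build_truth_table(table))
        assert diag.limited_diversity
        assert diag.remainder_fraction == 15 / 16


class TestExport:
    def test_frame_layout(self, breastfeeding, model1):
        frame = build_truth_table(breastfeeding, model1).to_frame()
        assert list(frame.columns) == [
            "Empowerment", "Design", "Lay-led", "n_cases", "outcome_class", "raw_consistency",
        ]
        remainder_rows = frame[frame["outcome_class"] == "remainder"]
        assert set(remainder_rows["raw_consistency"]) == {""}
        top = frame.iloc[0]
        assert top["raw_consistency"] == "1.000"
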