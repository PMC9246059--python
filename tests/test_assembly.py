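"""Rule assembly: compatibility matrix, templates, manual resolution."""

import itertools

import pytest

from logicnet import (
    LogicEdge,
    LogicLabel,
    PartialTruthTable,
    assemble_function,
    check_compatibility,
    check_implication,
    resolve_with_context,
    resolve_with_truth_table,
    semantic_equal,
)
from logicnet.expressions import evaluate, parse_expression, support
from logicnet.model import BooleanModel, Confidence, ModelError

from conftest import N, NI, S, SI, SN

BASIC = [S, N, SI, NI]

#: the published 4×4 compatibility matrix, row/column order S, N, SI, NI
MATRIX = {
    (S, S): True, (S, N): False, (S, SI): False, (S, NI): True,
    (N, S): False, (N, N): True, (N, SI): True, (N, NI): False,
    (SI, S): False, (SI, N): True, (SI, SI): True, (SI, NI): False,
    (NI, S): True, (NI, N): False, (NI, SI): False, (NI, NI): True,
}


@pytest.mark.parametrize("a,b", list(itertools.product(BASIC, BASIC)))
def test_compatibility_matrix_cell(a, b):
    ok, conflicts = check_compatibility([a, b])
    assert ok is MATRIX[(a, b)]
    if not ok:
        assert conflicts


def test_compatibility_is_symmetric():
    for a, b in itertools.product(BASIC, BASIC):
        assert check_compatibility([a, b])[0] == check_compatibility([b, a])[0]


def test_multiset_compatibility():
    ok, _ = check_compatibility([N, SI, N])
    assert ok
    ok, conflicts = check_compatibility([S, N])
    assert not ok and (S, N) in conflicts


def test_sufficient_and_necessary_must_be_alone():
    ok, _ = check_compatibility([SN])
    assert ok
    ok, _ = check_compatibility([SN, S])
    assert not ok


def test_unknown_label_rejected():
    with pytest.raises(ModelError):
        check_compatibility([LogicLabel.UNKNOWN, S])


class TestAssemble:
    def test_single_promoting_regulator(self):
        out = assemble_function("T", [LogicEdge("R", "T", "+", S)])
        assert str(out.function) == "T* = R"

    def test_single_inhibiting_regulator(self):
        out = assemble_function(
            "T", [LogicEdge("R", "T", "-", SI)]
        )
        assert str(out.function) == "T* = not R"

    def test_compatible_or_family(self):
        out = assemble_function(
            "T",
            [LogicEdge("R1", "T", "+", S), LogicEdge("R2", "T", "-", NI)],
        )
        assert out.status == "compatible"
        assert str(out.function) == "T* = R1 or not R2"

    def test_compatible_and_family(self):
        out = assemble_function(
            "T",
            [LogicEdge("R1", "T", "+", N), LogicEdge("R2", "T", "-", SI)],
        )
        assert str(out.function) == "T* = R1 and not R2"

    def test_template1_groups_necessary_side(self, two_suff_two_nec_edges):
        out = assemble_function("T", two_suff_two_nec_edges, "sufficient_dominant")
        assert out.status == "resolved_template1"
        assert str(out.function) == "T* = A or B or (C and D)"
        assert out.grouped == ["C", "D"]

    def test_template2_groups_sufficient_side(self, two_suff_two_nec_edges):
        out = assemble_function("T", two_suff_two_nec_edges, "necessary_dominant")
        assert out.status == "resolved_template2"
        assert semantic_equal(
            out.function.expression, parse_expression("(A or B) and C and D")
        )

    def test_template1_with_sufficient_inhibitor_in_group(self):
        edges = [
            LogicEdge("A", "T", "+", S),
            LogicEdge("B", "T", "+", S),
            LogicEdge("C", "T", "-", SI),
            LogicEdge("D", "T", "+", N),
        ]
        out = assemble_function("T", edges, "sufficient_dominant")
        assert str(out.function) == "T* = A or B or (not C and D)"

    def test_template2_with_necessary_inhibitor_in_group(self):
        edges = [
            LogicEdge("A", "T", "+", S),
            LogicEdge("B", "T", "-", NI),
            LogicEdge("C", "T", "+", N),
            LogicEdge("D", "T", "+", N),
        ]
        out = assemble_function("T", edges, "necessary_dominant")
        assert semantic_equal(
            out.function.expression,
            parse_expression("(A or not B) and C and D"),
        )

    def test_both_returns_two_candidates(self, two_suff_two_nec_edges):
        out = assemble_function("T", two_suff_two_nec_edges, "both")
        assert len(out.functions) == 2
        assert not semantic_equal(
            out.functions[0].expression, out.functions[1].expression
        )

    def test_sufficient_and_necessary_with_coregulators_unresolved(self):
        edges = [
            LogicEdge("R", "T", "+", SN),
            LogicEdge("Q", "T", "+", S),
        ]
        out = assemble_function("T", edges)
        assert out.status == "unresolved"
        assert not out.functions and out.conflicts

    def test_unknown_logic_joins_resolved_side(self):
        # sign-only regulator beside necessary regulators must not break
        # their necessity
        edges = [
            LogicEdge("A", "T", "+", N),
            LogicEdge("U", "T", "+", LogicLabel.UNKNOWN),
        ]
        out = assemble_function("T", edges)
        model = BooleanModel([out.function])
        assert check_implication(model, "A", N, "T")
        assert "U" in out.function.regulators

    def test_duplicate_sufficient_and_necessary_merge(self):
        edges = [
            LogicEdge("R", "T", "+", S),
            LogicEdge("R", "T", "+", N),
        ]
        out = assemble_function("T", edges)
        assert str(out.function) == "T* = R"

    def test_low_confidence_label_loses_tie(self):
        edges = [
            LogicEdge("A", "T", "+", S),
            LogicEdge("B", "T", "+", N, confidence=Confidence.LOW),
        ]
        out = assemble_function("T", edges)
        assert out.demoted == ["B"]
        model = BooleanModel([out.function])
        assert check_implication(model, "A", S, "T")

    def test_template_ordering_pointwise(self, two_suff_two_nec_edges):
        """Template 1 (OR-grouping) dominates template 2 pointwise."""
        out = assemble_function("T", two_suff_two_nec_edges, "both")
        f1, f2 = (f.expression for f in out.functions)
        variables = sorted(set(support(f1)) | set(support(f2)))
        for bits in itertools.product((0, 1), repeat=len(variables)):
            asg = dict(zip(variables, bits))
            assert evaluate(f1, asg) >= evaluate(f2, asg)

    def test_compatible_outcome_preserves_every_label(self):
        edge_sets = [
            [LogicEdge("A", "T", "+", S), LogicEdge("B", "T", "+", S),
             LogicEdge("C", "T", "-", NI)],
            [LogicEdge("A", "T", "+", N), LogicEdge("B", "T", "-", SI),
             LogicEdge("C", "T", "+", N)],
        ]
        for edges in edge_sets:
            out = assemble_function("T", edges)
            assert out.status == "compatible"
            model = BooleanModel([out.function])
            for e in edges:
                assert check_implication(model, e.regulator, e.logic, "T")

    def test_grouped_necessary_regulator_reading(self, two_suff_two_nec_edges):
        # clamping one grouped necessary regulator OFF with the sufficient
        # regulators OFF forces the target OFF
        out = assemble_function("T", two_suff_two_nec_edges, "sufficient_dominant")
        expr = out.function.expression
        assert evaluate(expr, {"A": 0, "B": 0, "C": 0, "D": 1}) == 0
        assert evaluate(expr, {"A": 0, "B": 0, "C": 1, "D": 0}) == 0


class TestContextResolution:
    def edges(self):
        return [
            LogicEdge("R1", "T", "+", N),
            LogicEdge("R2", "T", "+", S),
        ]

    def test_r2_assumed_off_gives_or(self):
        res = resolve_with_context("T", self.edges(), {"R1": {"R2": 0}})
        assert str(res.function) == "T* = R1 or R2"

    def test_r2_assumed_on_gives_and(self):
        res = resolve_with_context("T", self.edges(), {"R1": {"R2": 1}})
        assert str(res.function) == "T* = R1 and R2"

    def test_empty_context_with_consistent_labels_is_plain_assembly(self):
        edges = [
            LogicEdge("A", "T", "+", S),
            LogicEdge("B", "T", "+", S),
        ]
        res = resolve_with_context("T", edges, {})
        assert str(res.function) == str(assemble_function("T", edges).function)


class TestTruthTableResolution:
    def test_partial_rows_plus_label(self):
        tt = PartialTruthTable("T")
        tt.add_row({"R1": 0, "R2": 0}, 0)
        tt.add_row({"R1": 1, "R2": 0}, 1)
        res = resolve_with_truth_table(
            "T", tt, [LogicEdge("R2", "T", "+", S)]
        )
        assert str(res.function) == "T* = R1 or R2"
        assert res.n_candidates == 1

    def test_complete_table_fully_determines(self):
        tt = PartialTruthTable("T")
        for a in (0, 1):
            for b in (0, 1):
                tt.add_row({"R1": a, "R2": b}, int(a and b))
        res = resolve_with_truth_table("T", tt, [])
        assert str(res.function) == "T* = R1 and R2"

    def test_rows_contradicting_label_raise(self):
        tt = PartialTruthTable("T")
        tt.add_row({"R1": 1, "R2": 1}, 0)
        with pytest.raises(ModelError, match="conflicting row"):
            resolve_with_truth_table(
                "T", tt, [LogicEdge("R2", "T", "+", S)]
            )

    def test_contradictory_rows_rejected_at_entry(self):
        tt = PartialTruthTable("T")
        tt.add_row({"R1": 1}, 1)
        with pytest.raises(ModelError, match="contradictory"):
            tt.add_row({"R1": 1}, 0)
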