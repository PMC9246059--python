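"""Indirect-relationship integration and logic transitive reduction."""

import pytest

from logicnet import (
    BooleanFunction,
    BooleanModel,
    CorruptionConfig,
    GeneratorConfig,
    LogicEdge,
    LogicLabel,
    RegulatoryNetwork,
    check_implication,
    corrupt_statements,
    derive_statements,
    evidence_to_logic,
    generate_model,
    infer_from_statements,
    integrate_indirect,
    lbtr_reduce,
    suggest_mediators,
)
from logicnet.expressions import parse_expression, semantic_equal
from logicnet.model import Directness, ModelError

from conftest import INDEP, N, S, SHARED


def test_wrong_logic_path_adds_independent_edge(caim_network):
    model, net = caim_network
    pending = [LogicEdge("OST1", "CaIM", "+", S, directness=SHARED)]
    model2, actions = integrate_indirect(model, net, pending)
    assert actions[0].decision == "edge_to_target_new_path_needed"
    assert net.has_edge("OST1", "CaIM", "+")
    assert semantic_equal(
        model2.functions["CaIM"].expression,
        parse_expression(
            "ActinReorganization or (NtSyp121 and GHR1 and MRP5) "
            "or not ABH1 or not ERA1 or OST1"
        ),
    )
    assert check_implication(model2, "OST1", S, "CaIM")


def test_matching_necessary_path_adds_nothing(closure_chain):
    model, net = closure_chain
    pending = [LogicEdge("SLAC1", "Closure", "+", N, directness=SHARED)]
    _, actions = integrate_indirect(model, net, pending)
    assert actions[0].decision == "no_edge_path_exists"
    assert actions[0].evidence_path.path == (
        "SLAC1", "AnionEM", "H2O_Efflux", "Closure"
    )
    assert not net.has_edge("SLAC1", "Closure")


def test_matching_path_second_case(cgmp_chain):
    model, net = cgmp_chain
    pending = [LogicEdge("NOGC1", "8-nitro-cGMP", "+", N, directness=SHARED)]
    _, actions = integrate_indirect(model, net, pending)
    assert actions[0].decision == "no_edge_path_exists"
    assert not net.has_edge("NOGC1", "8-nitro-cGMP")


def test_no_path_no_anchor_adds_independent_edge():
    # an existing necessary regulator R; co-pointing not applicable; the
    # new sufficient regulator gets an independent edge
    net = RegulatoryNetwork(edges=[LogicEdge("R", "T", "+", N)])
    model = BooleanModel([BooleanFunction.parse("T", "R")], sources=["R", "SS"])
    net.nodes.add("SS")
    pending = [LogicEdge("SS", "T", "+", S, directness=SHARED)]
    model2, actions = integrate_indirect(model, net, pending)
    assert actions[0].decision == "edge_to_target_dominant"
    assert net.has_edge("SS", "T", "+")
    assert check_implication(model2, "SS", S, "T")
    # the conflicting necessary label is knowingly weakened and recorded
    assert actions[0].overridden == [("R", "T")]
    assert not check_implication(model2, "R", N, "T")


def test_anchor_completion_restores_upstream_edge():
    # S is indirectly sufficient for T; GLI-like anchor M regulates T with
    # the same label and pathway support is declared: complete S -> M
    net = RegulatoryNetwork(
        edges=[LogicEdge("M", "T", "+", S), LogicEdge("Q", "T", "+", S)]
    )
    model = BooleanModel(
        [BooleanFunction.parse("T", "M or Q")], sources=["M", "Q", "SS"]
    )
    net.nodes.add("SS")
    pending = [
        LogicEdge("SS", "T", "+", S, directness=SHARED, support_anchor="M")
    ]
    model2, actions = integrate_indirect(model, net, pending)
    assert actions[0].decision == "edge_to_upstream_regulator"
    assert actions[0].upstream_anchor == "M"
    assert net.has_edge("SS", "M", "+")
    assert not net.has_edge("SS", "T")
    assert check_implication(model2, "SS", S, "T")
    paths = suggest_mediators(actions[0], net)
    assert paths and paths[0].path == ("SS", "M", "T")


def test_anchor_completion_downstream_edge():
    # the outgoing mediator edge was lost: S -> M exists, M -> T is rebuilt
    net = RegulatoryNetwork(
        edges=[LogicEdge("SS", "M", "+", S), LogicEdge("Q", "T", "+", S)]
    )
    model = BooleanModel(
        [BooleanFunction.parse("M", "SS"), BooleanFunction.parse("T", "Q")],
        sources=["SS", "Q"],
    )
    pending = [
        LogicEdge("SS", "T", "+", S, directness=SHARED, support_anchor="M")
    ]
    model2, actions = integrate_indirect(model, net, pending)
    assert actions[0].decision == "edge_to_upstream_regulator"
    assert net.has_edge("M", "T", "+")
    assert check_implication(model2, "SS", S, "T")


def test_absent_endpoint_raises(closure_chain):
    model, net = closure_chain
    with pytest.raises(ModelError, match="absent"):
        integrate_indirect(
            model, net,
            [LogicEdge("nowhere", "Closure", "+", N, directness=SHARED)],
        )


def test_mediator_suggestions_for_realised_relationship(cgmp_chain):
    model, net = cgmp_chain
    pending = [LogicEdge("NOGC1", "8-nitro-cGMP", "+", N, directness=SHARED)]
    _, actions = integrate_indirect(model, net, pending)
    paths = suggest_mediators(actions[0], net)
    assert paths[0].mediators() == ("cGMP",)


def test_no_suggestions_for_compatible_edge_addition():
    net = RegulatoryNetwork(edges=[LogicEdge("Q", "T", "+", S)])
    model = BooleanModel([BooleanFunction.parse("T", "Q")],
                         sources=["Q", "SS"])
    net.nodes.add("SS")
    pending = [LogicEdge("SS", "T", "+", S, directness=SHARED)]
    _, actions = integrate_indirect(model, net, pending)
    assert actions[0].decision == "edge_to_target_compatible"
    assert suggest_mediators(actions[0], net) == []


class TestLbtr:
    def test_redundant_indirect_sufficient_edge_removed(self, snai1_network):
        model, net = snai1_network
        net2, removed = lbtr_reduce(model, net)
        assert [e.key for e in removed] == [("TCF/LEF", "SNAI1", "+")]
        assert not net2.has_edge("TCF/LEF", "SNAI1")
        # the implication survives through the path
        assert check_implication(model, "TCF/LEF", S, "SNAI1")

    def test_direct_edge_with_parallel_path_kept(self):
        edges = [
            LogicEdge("A", "M", "+", S),
            LogicEdge("M", "T", "+", S),
            LogicEdge("A", "T", "+", S),  # direct: never a candidate
        ]
        net = RegulatoryNetwork(edges=edges)
        model = BooleanModel(
            [BooleanFunction.parse("M", "A"),
             BooleanFunction.parse("T", "M or A")],
            sources=["A"],
        )
        _, removed = lbtr_reduce(model, net)
        assert removed == []
        assert net.has_edge("A", "T")

    def test_idempotent(self, snai1_network):
        model, net = snai1_network
        lbtr_reduce(model, net)
        _, removed_again = lbtr_reduce(model, net)
        assert removed_again == []

    def test_edge_count_never_grows(self, snai1_network):
        model, net = snai1_network
        before = len(net)
        net2, removed = lbtr_reduce(model, net)
        assert len(net2) == before - len(removed) <= before


def test_conservation_on_random_models_with_corruption():
    """Every accepted input implication holds on the final model."""
    for seed in range(10):
        truth = generate_model(GeneratorConfig(n_nodes=15, seed=seed))
        stmts = derive_statements(truth)
        stmts, _ = corrupt_statements(
            stmts, truth,
            CorruptionConfig(indirection_count=2, add_redundant_indirect=1,
                             seed=seed),
        )
        result = infer_from_statements(stmts)
        cons = result.report.conservation
        assert cons["violated"] == [], (seed, cons)
        assert cons["held"] == cons["checked"]
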