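"""Synthetic generator, observation derivation, corruption, scoring."""

import pytest

from logicnet import (
    BooleanFunction,
    BooleanModel,
    CorruptionConfig,
    GeneratorConfig,
    LogicLabel,
    corrupt_statements,
    derive_statements,
    generate_model,
    run_recovery_experiment,
    score_recovery,
)
from logicnet.expressions import essential_regulators
from logicnet.model import Directness, ModelError

from conftest import N, NI, S, SI, SN


def test_smallest_instance_is_single_edge():
    model = generate_model(GeneratorConfig(n_nodes=2, seed=1))
    assert len(model.sources) == 1
    (fn,) = model.functions.values()
    assert len(fn.regulators) == 1


def test_seed_determinism():
    a = generate_model(GeneratorConfig(n_nodes=20, seed=7))
    b = generate_model(GeneratorConfig(n_nodes=20, seed=7))
    assert str(a) == str(b)
    c = generate_model(GeneratorConfig(n_nodes=20, seed=8))
    assert str(a) != str(c)


@pytest.mark.parametrize("family", ["single_layer", "two_layer"])
def test_generated_rules_have_only_essential_regulators(family):
    model = generate_model(
        GeneratorConfig(n_nodes=20, max_in_degree=4,
                        function_family=family, seed=11)
    )
    for fn in model.functions.values():
        roles = essential_regulators(fn.expression)
        assert set(roles) == set(fn.regulators)
        assert "ambiguous" not in roles.values()


def test_invalid_configs_rejected():
    with pytest.raises(ModelError):
        GeneratorConfig(n_nodes=1)
    with pytest.raises(ModelError):
        GeneratorConfig(max_in_degree=0)
    with pytest.raises(ModelError):
        CorruptionConfig(drop_fraction=1.5)


class TestDeriveStatements:
    def test_sole_regulator_is_sufficient_and_necessary(self):
        model = BooleanModel([BooleanFunction.parse("T", "R")])
        (s,) = derive_statements(model)
        assert s.logic is SN and s.directness is Directness.DIRECT

    def test_or_rule_literals_are_sufficient(self):
        model = BooleanModel([BooleanFunction.parse("T", "A or B")])
        labels = {s.regulator: s.logic for s in derive_statements(model)}
        assert labels == {"A": S, "B": S}

    def test_and_rule_with_negation(self):
        model = BooleanModel([BooleanFunction.parse("T", "A and not B")])
        labels = {s.regulator: s.logic for s in derive_statements(model)}
        assert labels == {"A": N, "B": SI}

    def test_nested_group_members_are_sign_only(self):
        model = BooleanModel(
            [BooleanFunction.parse("T", "R1 or (R2 and R3)")]
        )
        by_reg = {s.regulator: s for s in derive_statements(model)}
        assert by_reg["R1"].logic is S
        for r in ("R2", "R3"):
            assert by_reg[r].logic is LogicLabel.UNKNOWN
            assert by_reg[r].sign == "+"

    def test_one_statement_per_edge(self):
        model = generate_model(GeneratorConfig(n_nodes=15, seed=2))
        stmts = derive_statements(model)
        assert len(stmts) == len(model.implied_edges())


class TestCorruption:
    def test_identity_when_nothing_requested(self):
        model = generate_model(GeneratorConfig(n_nodes=10, seed=4))
        stmts = derive_statements(model)
        out, manifest = corrupt_statements(
            stmts, model, CorruptionConfig(seed=1)
        )
        assert out == stmts
        assert not any(manifest.values())

    def test_drop_fraction_removes_expected_count(self):
        model = generate_model(GeneratorConfig(n_nodes=20, seed=4))
        stmts = derive_statements(model)
        out, manifest = corrupt_statements(
            stmts, model, CorruptionConfig(drop_fraction=0.2, seed=1)
        )
        assert len(out) == len(stmts) - round(0.2 * len(stmts))
        assert len(manifest["dropped"]) == round(0.2 * len(stmts))

    def test_redundant_indirect_statement_added_and_later_reduced(self):
        model = generate_model(GeneratorConfig(n_nodes=15, seed=6))
        stmts = derive_statements(model)
        out, manifest = corrupt_statements(
            stmts, model, CorruptionConfig(add_redundant_indirect=2, seed=3)
        )
        added = [s for s in out if s.directness is Directness.INDIRECT_INDEPENDENT]
        assert len(added) == 2 == len(manifest["redundant_added"])
        # the full pipeline must eliminate them again
        from logicnet import infer_from_statements

        result = infer_from_statements(out)
        for rec in manifest["redundant_added"]:
            assert not result.network.has_edge(rec["regulator"], rec["target"])

    def test_replacement_records_mediator_support(self):
        model = generate_model(GeneratorConfig(n_nodes=15, seed=6))
        stmts = derive_statements(model)
        out, manifest = corrupt_statements(
            stmts, model, CorruptionConfig(indirection_count=2, seed=3)
        )
        reps = manifest["replacements"]
        assert len(reps) == 2
        indirect = [s for s in out if s.directness is Directness.INDIRECT_SHARED]
        assert {s.support for s in indirect} == {r["mediator"] for r in reps}

    def test_requesting_too_many_paths_errors(self):
        model = BooleanModel([BooleanFunction.parse("T", "R")])
        stmts = derive_statements(model)
        with pytest.raises(ModelError, match="composable"):
            corrupt_statements(
                stmts, model, CorruptionConfig(indirection_count=5, seed=0)
            )


class TestScoring:
    def test_identical_models_score_one(self):
        m = generate_model(GeneratorConfig(n_nodes=10, seed=9))
        assert score_recovery(m, m).fraction == 1.0

    def test_single_wrong_rule(self):
        truth = BooleanModel(
            [BooleanFunction.parse("T", "A and B"),
             BooleanFunction.parse("U", "A")],
            sources=["A", "B"],
        )
        inferred = BooleanModel(
            [BooleanFunction.parse("T", "A or B"),
             BooleanFunction.parse("U", "A")],
            sources=["A", "B"],
        )
        sc = score_recovery(truth, inferred)
        assert (sc.n_nodes, sc.n_correct) == (2, 1)

    def test_commutated_rule_counts_correct(self):
        truth = BooleanModel([BooleanFunction.parse("T", "A or B")])
        inferred = BooleanModel([BooleanFunction.parse("T", "B or A")])
        assert score_recovery(truth, inferred).fraction == 1.0

    def test_missing_node_counts_incorrect(self):
        truth = BooleanModel(
            [BooleanFunction.parse("T", "A"), BooleanFunction.parse("U", "A")]
        )
        inferred = BooleanModel([BooleanFunction.parse("T", "A")])
        sc = score_recovery(truth, inferred)
        assert sc.verdicts["U"] is False


def test_full_input_round_trip_small():
    for seed in range(5):
        sc, _ = run_recovery_experiment(GeneratorConfig(n_nodes=12, seed=seed))
        assert sc.fraction == 1.0, (seed, sc.verdicts)


def test_two_layer_family_recovery_below_perfect_is_tolerated():
    # nested groups are observed sign-only; the method cannot reconstruct
    # the grouping, so recovery is typically below 1 — but the pipeline
    # must still run cleanly and conserve the retained implications
    sc, result = run_recovery_experiment(
        GeneratorConfig(n_nodes=15, function_family="two_layer", seed=3)
    )
    assert result.report.conservation["violated"] == []
    assert 0.0 <= sc.fraction <= 1.0
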