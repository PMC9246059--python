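"""Statement-table parsing and the distillation into labelled edges."""

import pytest

from logicnet import (
    CausalStatement,
    Confidence,
    Directness,
    LogicLabel,
    decompose_three_node,
    evidence_to_logic,
    parse_statements,
    statements_to_tsv,
)
from logicnet.model import ModelError

HEADER = (
    "kind\tregulator\tsign\ttarget\tlogic\tdirectness\tconfidence\t"
    "modulator\tmodulator_effect\tinner_effect\tevidence\tsupport\tcitation\n"
)


def parse_rows(*rows):
    return parse_statements(HEADER + "\n".join(rows) + ("\n" if rows else ""))


def test_pair_statement_round_trip():
    res = parse_rows(
        "pair\tABA\t+\tRCARs\tsufficient_and_necessary\tdirect\thigh"
        "\t\t\t\t\t\t"
    )
    assert len(res.statements) == 1 and not res.rejects
    s = res.statements[0]
    assert s.regulator == "ABA" and s.target == "RCARs"
    assert s.logic is LogicLabel.SUFFICIENT_AND_NECESSARY
    assert s.directness is Directness.DIRECT


def test_triple_statement_parses():
    res = parse_rows(
        "triple\t8-nitro-cGMP\t\tClosure\t\tindirect_independent\thigh\t"
        "ABA\tpromotes\tinduces\tknockout\t\t"
    )
    s = res.statements[0]
    assert s.kind == "triple" and s.modulator == "ABA"
    assert s.regulator == "8-nitro-cGMP" and s.target == "Closure"


def test_empty_file_with_header():
    res = parse_statements(HEADER)
    assert res.statements == [] and res.rejects == []


def test_missing_column_is_named():
    with pytest.raises(ModelError, match="regulator"):
        parse_statements("kind\ttarget\npair\tT\n")


def test_malformed_rows_collected_not_dropped():
    res = parse_rows(
        "pair\tA\t+\tT\tsufficient\tdirect\thigh\t\t\t\t\t\t",
        "pair\tA\t*\tT\t\tdirect\thigh\t\t\t\t\t\t",  # bad sign
        "frobnicate\tA\t+\tT\t\tdirect\thigh\t\t\t\t\t\t",  # bad kind
    )
    assert len(res.statements) == 1
    assert len(res.rejects) == 2
    # counts conserved: every row accounted for exactly once
    assert len(res.statements) + len(res.rejects) == 3


def test_duplicate_pairs_flagged():
    res = parse_rows(
        "pair\tA\t+\tT\tsufficient\tdirect\thigh\t\t\t\t\t\t",
        "pair\tA\t+\tT\tnecessary\tdirect\thigh\t\t\t\t\t\t",
    )
    assert len(res.statements) == 2
    assert res.duplicate_flags


def test_comment_lines_ignored():
    res = parse_statements(
        HEADER + "# a comment line\n"
        "pair\tA\t+\tT\tsufficient\tdirect\thigh\t\t\t\t\t\t\n"
    )
    assert len(res.statements) == 1


class TestEvidenceToLogic:
    def test_supply_implies_sufficient(self):
        s = CausalStatement("pair", "PA", "SPHK1/2", evidence="supply")
        assert evidence_to_logic(s).logic is LogicLabel.SUFFICIENT

    def test_knockout_implies_necessary(self):
        s = CausalStatement("pair", "Ca2+c", "PLDa1", evidence="knockout")
        assert evidence_to_logic(s).logic is LogicLabel.NECESSARY

    def test_blank_logic_other_evidence_keeps_sign_only(self):
        s = CausalStatement("pair", "X", "Y", sign="-", evidence="other")
        e = evidence_to_logic(s)
        assert e.sign == "-" and e.logic is LogicLabel.UNKNOWN

    def test_filled_logic_passes_through(self):
        s = CausalStatement(
            "pair", "R", "T", sign="-",
            logic=LogicLabel.SUFFICIENT_INHIBITORY, evidence="knockout",
        )
        assert evidence_to_logic(s).logic is LogicLabel.SUFFICIENT_INHIBITORY

    def test_reaction_evidence_marks_direct(self):
        s = CausalStatement(
            "pair", "R", "T", evidence="reaction",
            directness=Directness.INDIRECT_INDEPENDENT,
        )
        assert evidence_to_logic(s).directness is Directness.DIRECT

    def test_mapping_is_overridable(self):
        s = CausalStatement("pair", "R", "T", evidence="knockout")
        e = evidence_to_logic(s, {"knockout": "sufficient"})
        assert e.logic is LogicLabel.SUFFICIENT

    def test_low_confidence_propagates(self):
        s = CausalStatement(
            "pair", "R", "T", evidence="supply", confidence=Confidence.LOW
        )
        assert evidence_to_logic(s).confidence is Confidence.LOW


class TestDecomposeThreeNode:
    def triple(self, mod_eff="promotes", inner_eff="induces",
               evidence="knockout"):
        return CausalStatement(
            "triple", regulator="B", target="C", modulator="A",
            modulator_effect=mod_eff, inner_effect=inner_eff,
            evidence=evidence, directness=Directness.INDIRECT_INDEPENDENT,
        )

    def test_promotes_knockout(self):
        inner, mod = decompose_three_node(self.triple())
        assert inner.regulator == "B" and inner.logic is LogicLabel.SUFFICIENT
        assert mod.regulator == "A" and mod.logic is LogicLabel.NECESSARY
        assert mod.directness is Directness.INDIRECT_SHARED

    def test_inhibits_constitutive_activation(self):
        inner, mod = decompose_three_node(
            self.triple("inhibits", evidence="constitutive_activation")
        )
        assert inner.logic is LogicLabel.SUFFICIENT
        assert mod.logic is LogicLabel.SUFFICIENT_INHIBITORY

    def test_other_evidence_gives_sign_only_modulator(self):
        inner, mod = decompose_three_node(self.triple(evidence="other"))
        assert inner.logic is LogicLabel.SUFFICIENT
        assert mod.sign == "+" and mod.logic is LogicLabel.UNKNOWN

    def test_inner_inhibition_flips_signs(self):
        inner, mod = decompose_three_node(self.triple(inner_eff="inhibits"))
        assert inner.logic is LogicLabel.SUFFICIENT_INHIBITORY
        # A promotes an inhibition of C: net negative effect of A on C
        assert mod.sign == "-" and mod.logic is LogicLabel.NECESSARY_INHIBITORY

    def test_always_two_edges_inner_always_sufficient_type(self):
        for me in ("promotes", "inhibits"):
            for ie in ("induces", "inhibits"):
                for ev in ("knockout", "constitutive_activation", "other"):
                    out = decompose_three_node(self.triple(me, ie, ev))
                    assert len(out) == 2
                    assert out[0].logic in {
                        LogicLabel.SUFFICIENT,
                        LogicLabel.SUFFICIENT_INHIBITORY,
                    }

    def test_pair_statement_rejected(self):
        with pytest.raises(ModelError):
            decompose_three_node(CausalStatement("pair", "R", "T"))


def test_tsv_serialisation_round_trips():
    stmts = [
        CausalStatement("pair", "A", "T", sign="+",
                        logic=LogicLabel.SUFFICIENT),
        CausalStatement("triple", "B", "C", modulator="A",
                        modulator_effect="promotes", inner_effect="induces",
                        evidence="knockout", support="M"),
    ]
    res = parse_statements(statements_to_tsv(stmts))
    assert not res.rejects
    assert [(s.kind, s.regulator, s.target) for s in res.statements] == [
        ("pair", "A", "T"), ("triple", "B", "C")
    ]
    assert res.statements[1].support == "M"
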