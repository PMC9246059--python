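"""Parsing experimental causal statements and distilling them into edges.

Input is a tab-separated table, one statement per row.  Two-node
statements ("knockout of R abolishes T activity") become a single
labelled edge.  Three-node statements — "A promotes (B induces C)", the
shape of a typical mediator-perturbation experiment — decompose into two
derived pairwise statements: the inner relation B→C (sufficient-type) and
the modulator relation A→C, whose logic label follows from the kind of
perturbation applied to A.

TSV dialect
-----------
Columns: ``kind, regulator, sign, target, logic, directness, confidence,
modulator, modulator_effect, inner_effect, evidence, support, citation``.
UTF-8, ``#`` comment lines, header row required.  ``kind`` is ``pair`` or
``triple``; for triples, ``regulator`` holds the inner regulator (B),
``modulator`` the perturbed outer node (A) and ``target`` the readout
(C).  ``support`` optionally names a mediator node for which the
literature documents a pathway from the regulator (used when deciding
whether to complete a path rather than add an independent edge).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .labels import LogicLabel
from .model import Confidence, Directness, LogicEdge, ModelError

__all__ = [
    "CausalStatement",
    "ParseResult",
    "parse_statements",
    "decompose_three_node",
    "evidence_to_logic",
    "statements_to_tsv",
    "EVIDENCE_VOCAB",
]

EVIDENCE_VOCAB = {
    "knockout",
    "constitutive_activation",
    "supply",
    "reaction",
    "physical_interaction",
    "other",
}

_COLUMNS = [
    "kind",
    "regulator",
    "sign",
    "target",
    "logic",
    "directness",
    "confidence",
    "modulator",
    "modulator_effect",
    "inner_effect",
    "evidence",
    "support",
    "citation",
]


@dataclass(frozen=True)
class CausalStatement:
    kind: str  # 'pair' | 'triple'
    regulator: str  # pair: R; triple: the inner regulator B
    target: str
    sign: str = "+"  # pair only
    logic: LogicLabel = LogicLabel.UNKNOWN
    directness: Directness = Directness.DIRECT
    confidence: Confidence = Confidence.HIGH
    modulator: str = ""  # triple: the perturbed node A
    modulator_effect: str = ""  # 'promotes' | 'inhibits'
    inner_effect: str = ""  # 'induces' | 'inhibits'
    evidence: str = "other"
    support: str = ""  # declared pathway-support anchor node
    citation: str = ""
    line: int = 0  # provenance: 1-based data-row number


@dataclass
class ParseResult:
    statements: list[CausalStatement] = field(default_factory=list)
    #: (line number, raw row dict, reason) — malformed rows are collected,
    #: never silently dropped
    rejects: list[tuple[int, dict, str]] = field(default_factory=list)
    #: duplicate (regulator, target) pairs flagged for assembly-time merging
    duplicate_flags: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.statements)


def _clean(v) -> str:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return ""
    return str(v).strip()


def parse_statements(table: str) -> ParseResult:
    """Parse the statement TSV dialect from text.

    Every input row lands either in ``statements`` or in ``rejects`` with
    its line number and a reason; counts are conserved.
    """
    df = pd.read_csv(
        io.StringIO(table), sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    missing = [c for c in ("kind", "regulator", "target") if c not in df.columns]
    if missing:
        raise ModelError(f"statement table missing required column(s): {missing}")
    result = ParseResult()
    seen_pairs: dict[tuple[str, str], list[int]] = {}
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        get = lambda c: _clean(row.get(c))
        kind = get("kind").lower()
        try:
            if kind not in {"pair", "triple"}:
                raise ModelError(f"unknown kind {kind!r}")
            evidence = get("evidence") or "other"
            if evidence not in EVIDENCE_VOCAB:
                raise ModelError(f"unknown evidence type {evidence!r}")
            logic_txt = get("logic")
            logic = LogicLabel(logic_txt) if logic_txt else LogicLabel.UNKNOWN
            directness = Directness(get("directness") or "direct")
            confidence = Confidence(get("confidence") or "high")
            regulator, target = get("regulator"), get("target")
            if not regulator or not target:
                raise ModelError("regulator and target are required")
            if kind == "pair":
                sign = get("sign") or logic.sign
                if sign not in {"+", "-"}:
                    raise ModelError(f"bad sign {sign!r}")
                if logic is not LogicLabel.UNKNOWN and logic.sign != sign:
                    raise ModelError(
                        f"sign {sign!r} contradicts logic {logic.value!r}"
                    )
                stmt = CausalStatement(
                    kind="pair",
                    regulator=regulator,
                    target=target,
                    sign=sign,
                    logic=logic,
                    directness=directness,
                    confidence=confidence,
                    evidence=evidence,
                    support=get("support"),
                    citation=get("citation"),
                    line=i,
                )
            else:
                modulator = get("modulator")
                mod_eff = get("modulator_effect")
                inner_eff = get("inner_effect") or "induces"
                if not modulator:
                    raise ModelError("triple statement requires a modulator")
                if mod_eff not in {"promotes", "inhibits"}:
                    raise ModelError(f"bad modulator_effect {mod_eff!r}")
                if inner_eff not in {"induces", "inhibits"}:
                    raise ModelError(f"bad inner_effect {inner_eff!r}")
                stmt = CausalStatement(
                    kind="triple",
                    regulator=regulator,
                    target=target,
                    directness=directness,
                    confidence=confidence,
                    modulator=modulator,
                    modulator_effect=mod_eff,
                    inner_effect=inner_eff,
                    evidence=evidence,
                    support=get("support"),
                    citation=get("citation"),
                    line=i,
                )
        except (ModelError, ValueError) as exc:
            result.rejects.append((i, row, str(exc)))
            continue
        if stmt.kind == "pair":
            key = (stmt.regulator, stmt.target)
            if key in seen_pairs:
                result.duplicate_flags.append(
                    f"duplicate pair statement {key[0]} -> {key[1]} "
                    f"(lines {seen_pairs[key] + [i]})"
                )
            seen_pairs.setdefault(key, []).append(i)
        result.statements.append(stmt)
    return result


# -- evidence → logic mapping (table-driven, overridable) -------------------

#: For a pair statement with a blank logic column: evidence type → the
#: (trigger, forced-agrees-with-sign) implication it warrants.  A knockout
#: that abolishes the target is the classic "necessary" call; sustained
#: supply or constitutive activation that drives the target is
#: "sufficient".  Reaction/physical-interaction evidence speaks to
#: directness, not logic.
DEFAULT_PAIR_EVIDENCE_MAP: dict[str, str] = {
    "knockout": "necessary",
    "constitutive_activation": "sufficient",
    "supply": "sufficient",
}

_SIGNED = {
    ("necessary", "+"): LogicLabel.NECESSARY,
    ("necessary", "-"): LogicLabel.NECESSARY_INHIBITORY,
    ("sufficient", "+"): LogicLabel.SUFFICIENT,
    ("sufficient", "-"): LogicLabel.SUFFICIENT_INHIBITORY,
}


def evidence_to_logic(
    stmt: CausalStatement,
    evidence_map: Mapping[str, str] | None = None,
) -> LogicEdge:
    """Turn a pair statement into a labelled edge.

    A filled logic column passes through untouched.  Otherwise the label
    is derived from the evidence type and sign; reaction / physical
    interaction evidence marks the edge direct without assigning logic.
    """
    if stmt.kind != "pair":
        raise ModelError("evidence_to_logic expects a pair statement")
    emap = dict(DEFAULT_PAIR_EVIDENCE_MAP)
    if evidence_map:
        emap.update(evidence_map)
    logic = stmt.logic
    directness = stmt.directness
    if logic is LogicLabel.UNKNOWN:
        family = emap.get(stmt.evidence)
        if family is not None:
            logic = _SIGNED[(family, stmt.sign)]
    if stmt.evidence in {"reaction", "physical_interaction"}:
        directness = Directness.DIRECT
    if logic is not LogicLabel.UNKNOWN and logic.sign != stmt.sign:
        raise ModelError(
            f"statement line {stmt.line}: sign {stmt.sign!r} contradicts "
            f"derived logic {logic.value!r}"
        )
    return LogicEdge(
        regulator=stmt.regulator,
        target=stmt.target,
        sign=stmt.sign,
        logic=logic,
        directness=directness,
        confidence=stmt.confidence,
        provenance=stmt.citation or f"line {stmt.line}",
        support_anchor=stmt.support or None,
    )


def decompose_three_node(stmt: CausalStatement) -> list[LogicEdge]:
    """Decompose "A promotes/inhibits (B induces/inhibits C)".

    Emits exactly two edges:

    1. the inner relation B→C, sufficient (or sufficient-inhibitory when B
       inhibits C), with the statement's directness flag;
    2. the modulator relation A→C, whose sign is the product of the
       modulator's and the inner relation's signs and whose label follows
       from the perturbation: a knockout of A that silences the readout
       makes A necessary(-inhibitory); constitutive activation of A that
       silences it makes A a sufficient inhibitor (sufficient, for the
       promoting composite).  Any other evidence yields sign-only
       (unknown logic).  The modulator edge is tagged mediator-sharing so
       it enters the path/subgraph integration step.
    """
    if stmt.kind != "triple":
        raise ModelError("decompose_three_node expects a triple statement")
    prov = stmt.citation or f"line {stmt.line}"
    inner_logic = (
        LogicLabel.SUFFICIENT
        if stmt.inner_effect == "induces"
        else LogicLabel.SUFFICIENT_INHIBITORY
    )
    inner = LogicEdge(
        regulator=stmt.regulator,
        target=stmt.target,
        sign=inner_logic.sign,
        logic=inner_logic,
        directness=stmt.directness,
        confidence=stmt.confidence,
        provenance=prov,
    )
    mod_sign = "+" if (stmt.modulator_effect == "promotes") == (
        stmt.inner_effect == "induces"
    ) else "-"
    mod_logic = LogicLabel.UNKNOWN
    if stmt.evidence == "knockout":
        mod_logic = _SIGNED[("necessary", mod_sign)]
    elif stmt.evidence in {"constitutive_activation", "supply"}:
        mod_logic = _SIGNED[("sufficient", mod_sign)]
    modulator = LogicEdge(
        regulator=stmt.modulator,
        target=stmt.target,
        sign=mod_sign,
        logic=mod_logic,
        directness=Directness.INDIRECT_SHARED,
        confidence=stmt.confidence,
        provenance=prov,
        support_anchor=stmt.support or None,
    )
    return [inner, modulator]


def statements_to_tsv(statements: Iterable[CausalStatement]) -> str:
    """Serialize statements back to the TSV dialect (round-trippable)."""
    rows = []
    for s in statements:
        rows.append(
            {
                "kind": s.kind,
                "regulator": s.regulator,
                "sign": s.sign if s.kind == "pair" else "",
                "target": s.target,
                "logic": "" if s.logic is LogicLabel.UNKNOWN else s.logic.value,
                "directness": s.directness.value,
                "confidence": s.confidence.value,
                "modulator": s.modulator,
                "modulator_effect": s.modulator_effect,
                "inner_effect": s.inner_effect,
                "evidence": s.evidence,
                "support": s.support,
                "citation": s.citation,
            }
        )
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return df.to_csv(sep="\t", index=False)
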