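"""End-to-end inference: statements in, Boolean model + report out.

Stage order: parse → decompose triples → evidence→logic → iterated
co-pointing inference → per-target rule assembly (direct and
independent-indirect edges) → integration of mediator-sharing indirect
relationships → logic binary transitive reduction → final conservation
check that every retained implication holds on the finished model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .algebra import DEFAULT_MAX_PATH_LEN, check_implication
from .assembly import AssemblyOutcome, Resolution, assemble_function, \
    resolve_with_context, resolve_with_truth_table
from .copointing import CopointingInference, apply_copointing
from .integration import IntegrationAction, integrate_indirect, lbtr_reduce
from .labels import LogicLabel, label_from_pairs
from .model import (
    BooleanModel,
    Directness,
    LogicEdge,
    ModelError,
    PartialTruthTable,
    RegulatoryNetwork,
)
from .statements import (
    CausalStatement,
    ParseResult,
    decompose_three_node,
    evidence_to_logic,
    parse_statements,
)

__all__ = ["InferenceReport", "PipelineResult", "infer_from_statements",
           "run_pipeline"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class InferenceReport:
    schema_version: int = REPORT_SCHEMA_VERSION
    counts: dict = field(default_factory=dict)
    per_target: dict = field(default_factory=dict)
    integration_log: list = field(default_factory=list)
    copointing: list = field(default_factory=list)
    conservation: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate_counts(self) -> None:
        c = self.counts
        resolved = (
            c["resolutions"]["template1"]
            + c["resolutions"]["template2"]
            + c["resolutions"]["manual"]
            + c["resolutions"]["unresolved"]
        )
        if resolved != c["incompatible_targets"]:
            raise ModelError(
                "report inconsistency: resolutions do not sum to the number "
                "of incompatible targets"
            )


@dataclass
class PipelineResult:
    model: BooleanModel
    network: RegulatoryNetwork
    report: InferenceReport
    outcomes: dict[str, AssemblyOutcome]
    actions: list[IntegrationAction]
    inferences: list[CopointingInference]
    ok: bool = True


def _merge_network_edges(edges: Sequence[LogicEdge]) -> list[LogicEdge]:
    """One edge per (regulator, target, sign), with merged labels."""
    grouped: dict[tuple[str, str, str], list[LogicEdge]] = {}
    for e in edges:
        grouped.setdefault(e.key, []).append(e)
    out = []
    for key in sorted(grouped):
        group = grouped[key]
        pairs = set()
        for e in group:
            pairs.update(e.logic.pairs)
        label = label_from_pairs(pairs) or group[0].logic
        anchor = next((e.support_anchor for e in group if e.support_anchor),
                      None)
        out.append(dataclasses.replace(group[0], logic=label,
                                       support_anchor=anchor))
    return out


def infer_from_statements(
    statements: Sequence[CausalStatement],
    template: str = "sufficient_dominant",
    max_path_len: int = DEFAULT_MAX_PATH_LEN,
    truth_tables: Mapping[str, PartialTruthTable] | None = None,
    contexts: Mapping[str, Mapping[str, Mapping[str, int]]] | None = None,
    evidence_map: Mapping[str, str] | None = None,
    parse_result: ParseResult | None = None,
) -> PipelineResult:
    """Run the full inference pipeline on distilled statements.

    ``truth_tables`` maps a target to a partial truth table for manual
    resolution; ``contexts`` maps a target to per-regulator assumed
    co-regulator states.  Unresolvable targets are reported, not fatal.
    """
    statements = list(statements)
    truth_tables = dict(truth_tables or {})
    contexts = dict(contexts or {})
    report = InferenceReport()
    warnings = report.warnings

    # 1-2. distil statements into labelled edges
    edges: list[LogicEdge] = []
    for stmt in statements:
        try:
            if stmt.kind == "triple":
                edges.extend(decompose_three_node(stmt))
            else:
                edges.append(evidence_to_logic(stmt, evidence_map))
        except ModelError as exc:
            warnings.append(f"statement line {stmt.line}: {exc}")
    nodes = {e.regulator for e in edges} | {e.target for e in edges}

    # 3. iterated co-pointing inference
    all_edges = list(edges)
    inferences: list[CopointingInference] = []
    for _ in range(max(1, len(nodes))):
        network0 = RegulatoryNetwork(nodes, _merge_network_edges(all_edges))
        new = apply_copointing(all_edges, network0)
        fresh = []
        existing = {e.key for e in all_edges}
        for inf in new:
            if inf.inferred.key in existing:
                continue
            fresh.append(inf)
            existing.add(inf.inferred.key)
            # the conflicting indirect sufficient-type edge is now expected
            # to be mediated through the inferred target: reclassify it as
            # mediator-sharing so it enters the integration step
            for i, e in enumerate(all_edges):
                if (
                    e.regulator == inf.sufficient_node
                    and e.target == inf.shared_target
                    and e.logic.is_sufficient_type
                    and e.directness is Directness.INDIRECT_INDEPENDENT
                ):
                    all_edges[i] = dataclasses.replace(
                        e, directness=Directness.INDIRECT_SHARED
                    )
        if not fresh:
            break
        inferences.extend(fresh)
        all_edges.extend(inf.inferred for inf in fresh)
    report.copointing = [
        {
            "sufficient_node": inf.sufficient_node,
            "necessary_node": inf.necessary_node,
            "shared_target": inf.shared_target,
            "inferred": str(inf.inferred),
        }
        for inf in inferences
    ]

    # 4. partition
    assembly_edges = [
        e for e in all_edges if e.directness is not Directness.INDIRECT_SHARED
    ]
    pending = [
        e for e in all_edges if e.directness is Directness.INDIRECT_SHARED
    ]

    # 5. per-target assembly
    by_target: dict[str, list[LogicEdge]] = {}
    for e in assembly_edges:
        by_target.setdefault(e.target, []).append(e)
    outcomes: dict[str, AssemblyOutcome] = {}
    functions = []
    n_incompatible = 0
    resolutions = {"template1": 0, "template2": 0, "manual": 0,
                   "unresolved": 0}
    for target in sorted(by_target):
        tedges = by_target[target]
        try:
            if target in truth_tables:
                res = resolve_with_truth_table(
                    target, truth_tables[target], tedges, template
                )
                outcome = AssemblyOutcome(
                    target, "resolved_manual", [res.function],
                    notes=list(res.notes),
                )
                if res.ambiguous:
                    outcome.notes.append(
                        f"{res.n_candidates} candidate rules existed"
                    )
            elif target in contexts:
                res = resolve_with_context(
                    target, tedges, contexts[target], template
                )
                outcome = AssemblyOutcome(
                    target, "resolved_manual", [res.function],
                    notes=list(res.notes),
                )
            else:
                outcome = assemble_function(target, tedges, template)
        except ModelError as exc:
            outcome = AssemblyOutcome(target, "unresolved",
                                      notes=[str(exc)])
            warnings.append(f"target {target}: {exc}")
        outcomes[target] = outcome
        if outcome.status != "compatible" or outcome.conflicts:
            if outcome.conflicts or outcome.status in {
                "resolved_template1", "resolved_template2",
                "resolved_manual", "unresolved",
            }:
                n_incompatible += 1
                key = {
                    "resolved_template1": "template1",
                    "resolved_template2": "template2",
                    "resolved_manual": "manual",
                    "unresolved": "unresolved",
                }.get(outcome.status)
                if key:
                    resolutions[key] += 1
        if outcome.function is not None:
            functions.append(outcome.function)

    network = RegulatoryNetwork(nodes, _merge_network_edges(assembly_edges))
    model = BooleanModel(
        functions,
        sources=sorted(nodes - {f.target for f in functions}),
    )

    # 6. integrate mediator-sharing indirect relationships
    pending_merged = _merge_network_edges(pending)
    model, actions = integrate_indirect(
        model, network, pending_merged, max_path_len
    )
    n_added = sum(1 for a in actions if a.added_edge is not None)
    inferred_keys = {inf.inferred.key for inf in inferences}
    copointing_new_edges = sum(
        1 for a in actions
        if a.added_edge is not None and a.relationship.key in inferred_keys
    )

    # 7. reduction
    network, removed = lbtr_reduce(model, network, max_path_len)

    # 8. conservation: every retained implication must hold
    weakened: set[tuple[str, str]] = set()
    for target, outcome in outcomes.items():
        for reg in outcome.grouped + outcome.demoted:
            weakened.add((reg, target))
    for action in actions:
        weakened.update(action.overridden)
    held, violated = 0, []
    checked = 0
    model_nodes = model.nodes
    for e in _merge_network_edges(all_edges):
        if e.logic is LogicLabel.UNKNOWN or not e.logic.pairs:
            continue
        if (e.regulator, e.target) in weakened:
            continue
        if outcomes.get(e.target) is not None and not outcomes[e.target].functions \
                and e.directness is not Directness.INDIRECT_SHARED:
            continue  # unresolved target: nothing to check against
        if e.regulator not in model_nodes or e.target not in model_nodes:
            violated.append(str(e))
            continue
        checked += 1
        if check_implication(model, e.regulator, e.logic, e.target):
            held += 1
        else:
            violated.append(str(e))
    report.conservation = {
        "checked": checked,
        "held": held,
        "violated": violated,
    }

    # 9. report
    report.counts = {
        "statements": len(statements),
        "rejected_rows": len(parse_result.rejects) if parse_result else 0,
        "pairwise_implications": len(edges),
        "implications_with_logic": sum(
            1 for e in edges if e.logic is not LogicLabel.UNKNOWN
        ),
        "copointing_inferences": len(inferences),
        "copointing_new_edges": copointing_new_edges,
        "incompatible_targets": n_incompatible,
        "resolutions": resolutions,
        "edges_added": n_added,
        "edges_removed_lbtr": len(removed),
        "final_edges": len(network),
        "final_rules": len(model.functions),
    }
    if parse_result:
        for lineno, _row, reason in parse_result.rejects:
            warnings.append(f"rejected row {lineno}: {reason}")
    report.per_target = {
        t: {
            "status": o.status,
            "rules": [str(f) for f in o.functions],
            "conflicts": o.conflicts,
            "grouped": o.grouped,
            "demoted": o.demoted,
            "notes": o.notes,
        }
        for t, o in outcomes.items()
    }
    report.integration_log = [
        {
            "relationship": str(a.relationship),
            "decision": a.decision,
            "evidence_path": str(a.evidence_path) if a.evidence_path else None,
            "upstream_anchor": a.upstream_anchor,
            "added_edge": str(a.added_edge) if a.added_edge else None,
            "notes": a.notes,
        }
        for a in actions
    ]
    report.validate_counts()
    ok = not violated and resolutions["unresolved"] == 0
    return PipelineResult(
        model=model,
        network=network,
        report=report,
        outcomes=outcomes,
        actions=actions,
        inferences=inferences,
        ok=ok,
    )


def run_pipeline(
    statements_path,
    template: str = "sufficient_dominant",
    max_path_len: int = DEFAULT_MAX_PATH_LEN,
    truth_tables: Mapping[str, PartialTruthTable] | None = None,
    contexts=None,
    evidence_map=None,
) -> PipelineResult:
    """File-level entry point: parse a statement TSV and infer."""
    text = Path(statements_path).read_text(encoding="utf-8")
    parsed = parse_statements(text)
    result = infer_from_statements(
        parsed.statements,
        template=template,
        max_path_len=max_path_len,
        truth_tables=truth_tables,
        contexts=contexts,
        evidence_map=evidence_map,
        parse_result=parsed,
    )
    for flag in parsed.duplicate_flags:
        result.report.warnings.append(flag)
    return result
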