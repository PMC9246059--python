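"""Integrating mediator-sharing indirect relationships; network reduction.

After the draft model is assembled from direct and independent-indirect
edges, each remaining indirect relationship S→T is evaluated against the
model:

* it may already be realised by a path or subgraph of the same causal
  logic (semantic check via the forced-state oracle) — nothing is added;
* a path may exist but with the wrong logic — an independent edge is
  added to satisfy the stated implication;
* with no path at all, a declared pathway-support anchor lets us complete
  a path through an existing regulator instead of wiring S straight to T;
* otherwise an independent edge S→T is added.

Added regulators join the target's rule with the operator of their label
family; when the label conflicts with the existing regulators the new
regulator is made dominant (canalizing at the top of the rule), which is
the same rewrite.  Finally, logic binary transitive reduction (l-BTR)
removes non-direct edges that are redundant because a path of the same
sign and causal logic exists, re-verifying after each removal that every
implication that held before still holds, and rolling back otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .algebra import (
    DEFAULT_MAX_PATH_LEN,
    PathImplication,
    check_implication,
    find_supporting_paths,
)
from .expressions import And, Expr, Lit, Or, canonicalize
from .labels import LogicLabel
from .model import (
    BooleanFunction,
    BooleanModel,
    Directness,
    LogicEdge,
    ModelError,
    RegulatoryNetwork,
)

__all__ = [
    "IntegrationAction",
    "integrate_indirect",
    "lbtr_reduce",
    "suggest_mediators",
]


@dataclass
class IntegrationAction:
    relationship: LogicEdge
    decision: str  # no_edge_path_exists | edge_to_target_new_path_needed |
    #               edge_to_target_compatible | edge_to_target_dominant |
    #               edge_to_upstream_regulator
    evidence_path: PathImplication | None = None
    upstream_anchor: str | None = None
    added_edge: LogicEdge | None = None
    #: (regulator, target) labels the dominant addition knowingly weakened
    overridden: list[tuple[str, str]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def _forced_of(label: LogicLabel) -> int | None:
    if label.is_basic:
        return label.pairs[0][1]
    return None


def _join_rule(
    model: BooleanModel, target: str, regulator: str, sign: str, or_family: bool
) -> None:
    """Attach a regulator to a rule with its family operator.

    Forced-to-1 labels OR-join (plain literal for '+', negated for '-');
    forced-to-0 labels AND-join.  The new literal sits at the top of the
    rule, i.e. the new regulator is canalizing (dominant) for the target.
    """
    lit = Lit(regulator, sign == "-")
    old = model.functions.get(target)
    if old is None:
        expr: Expr = lit
    elif regulator in old.regulators:
        return  # already wired in
    elif or_family:
        expr = canonicalize(Or((old.expression, lit)))
    else:
        expr = canonicalize(And((old.expression, lit)))
    model.set_function(BooleanFunction(target, expr))


def _holds(model: BooleanModel, edge: LogicEdge) -> bool:
    if not edge.logic.pairs:
        return False
    nodes = model.nodes
    if edge.regulator not in nodes or edge.target not in nodes:
        return False
    return check_implication(model, edge.regulator, edge.logic, edge.target)


def _existing_labels(network: RegulatoryNetwork, target: str) -> list[LogicLabel]:
    return [
        e.logic
        for e in network.in_edges(target)
        if e.logic is not LogicLabel.UNKNOWN
    ]


def _conflicting_edges(
    network: RegulatoryNetwork, target: str, label: LogicLabel
) -> list[LogicEdge]:
    f = _forced_of(label)
    if f is None:
        return network.in_edges(target)
    return [
        e for e in network.in_edges(target)
        if any(other != f for _, other in e.logic.pairs)
    ]




def _add_edge(
    model: BooleanModel, network: RegulatoryNetwork, edge: LogicEdge
) -> LogicEdge:
    placed = LogicEdge(
        regulator=edge.regulator,
        target=edge.target,
        sign=edge.sign,
        logic=edge.logic,
        directness=Directness.INDIRECT_INDEPENDENT,
        confidence=edge.confidence,
        provenance=f"integration: {edge.provenance}".strip(": "),
    )
    if not network.has_edge(placed.regulator, placed.target, placed.sign):
        network.add_edge(placed)
    forced = _forced_of(edge.logic)
    if forced is None:
        # sign-only or sufficient-and-necessary: join by sign family
        or_family = edge.sign == "+"
    else:
        or_family = forced == 1
    _join_rule(model, placed.target, placed.regulator, placed.sign, or_family)
    return placed


def _try_anchor_completion(
    model: BooleanModel,
    network: RegulatoryNetwork,
    pending: LogicEdge,
    action: IntegrationAction,
) -> bool:
    """Complete a path through a declared pathway-support anchor.

    If the anchor M regulates T with label m such that some l1 composes
    with m to the pending label L, add S→M (l1).  Symmetrically, if an
    edge S→M with label l1 exists, add M→T with the l2 completing the
    chain.  Requires basic labels throughout.
    """
    anchor = pending.support_anchor
    if not anchor or not pending.logic.is_basic:
        return False
    (tL, fL) = pending.logic.pairs[0]
    s, t = pending.regulator, pending.target
    from .labels import _FROM_PAIR  # single source of truth for pair names

    # upstream: anchor regulates the target
    for m_edge in network.edges_between(anchor, t):
        for tm, fm in m_edge.logic.pairs:
            if fm == fL:
                l1 = _FROM_PAIR[(tL, tm)]
                new = LogicEdge(s, anchor, l1.sign, l1,
                                provenance=pending.provenance)
                action.decision = "edge_to_upstream_regulator"
                action.upstream_anchor = anchor
                action.added_edge = _add_edge(model, network, new)
                action.evidence_path = PathImplication(
                    (s, anchor, t), pending.logic
                )
                action.notes.append(
                    f"completed path via declared support anchor {anchor}"
                )
                return True
    # downstream: an edge from S to the anchor exists
    for s_edge in network.edges_between(s, anchor):
        for ts, fs in s_edge.logic.pairs:
            if ts == tL:
                l2 = _FROM_PAIR[(fs, fL)]
                new = LogicEdge(anchor, t, l2.sign, l2,
                                provenance=pending.provenance)
                action.decision = "edge_to_upstream_regulator"
                action.upstream_anchor = anchor
                action.added_edge = _add_edge(model, network, new)
                action.evidence_path = PathImplication(
                    (s, anchor, t), pending.logic
                )
                action.notes.append(
                    f"completed path downstream of support anchor {anchor}"
                )
                return True
    return False


def _any_path(network: RegulatoryNetwork, s: str, t: str) -> bool:
    return network.has_path(s, t)


def integrate_indirect(
    model: BooleanModel,
    network: RegulatoryNetwork,
    pending: Sequence[LogicEdge],
    max_len: int = DEFAULT_MAX_PATH_LEN,
) -> tuple[BooleanModel, list[IntegrationAction]]:
    """Incorporate mediator-sharing indirect relationships one by one.

    Processes pending edges in deterministic (target, regulator) order;
    the model and network are updated in place on a copy and returned.
    """
    model = model.copy()
    nodes = model.nodes | network.nodes
    for e in pending:
        if e.regulator not in nodes or e.target not in nodes:
            raise ModelError(
                f"pending edge {e.regulator}->{e.target} has endpoints "
                "absent from the model/network"
            )
    actions: list[IntegrationAction] = []
    for e in sorted(pending, key=lambda e: (e.target, e.regulator, e.sign)):
        action = IntegrationAction(relationship=e, decision="")
        if e.logic is LogicLabel.UNKNOWN:
            # sign-only relationship: an existing same-sign path satisfies it
            if _signed_path_exists(network, e.regulator, e.target, e.sign,
                                   max_len):
                action.decision = "no_edge_path_exists"
                action.notes.append("sign-only relationship matched by a path")
            else:
                action.decision = "edge_to_target_compatible"
                action.added_edge = _add_edge(model, network, e)
                action.notes.append("sign-only relationship added as an edge")
            actions.append(action)
            continue
        if _holds(model, e):
            action.decision = "no_edge_path_exists"
            paths = find_supporting_paths(
                network, e.regulator, e.target, e.logic, max_len
            )
            if paths:
                action.evidence_path = paths[0]
            else:
                action.notes.append(
                    "implication holds via a subgraph (no single supporting "
                    "path)"
                )
        elif _any_path(network, e.regulator, e.target):
            # a path exists but its logic does not match: independent edge
            action.decision = "edge_to_target_new_path_needed"
            conflicting = _conflicting_edges(network, e.target, e.logic)
            action.added_edge = _add_edge(model, network, e)
            if conflicting:
                action.overridden = sorted(
                    (c.regulator, c.target) for c in conflicting
                    if c.logic is not LogicLabel.UNKNOWN
                )
                action.notes.append("added regulator made dominant")
        elif _try_anchor_completion(model, network, e, action):
            pass
        else:
            conflicting = _conflicting_edges(network, e.target, e.logic)
            if not conflicting:
                action.decision = "edge_to_target_compatible"
            else:
                action.decision = "edge_to_target_dominant"
                action.overridden = sorted(
                    (c.regulator, c.target) for c in conflicting
                    if c.logic is not LogicLabel.UNKNOWN
                )
                action.notes.append("added regulator made dominant")
            action.added_edge = _add_edge(model, network, e)
        if action.added_edge is not None and e.logic.pairs and not _holds(
            model, e
        ):
            action.notes.append(
                "warning: implication still unrealised after edge addition"
            )
        actions.append(action)
    return model, actions


def _signed_path_exists(
    network: RegulatoryNetwork, s: str, t: str, sign: str, max_len: int
) -> bool:
    if s == t or s not in network.nodes or t not in network.nodes:
        return False
    import networkx as nx

    g = network.to_networkx()
    want = 1 if sign == "+" else -1
    signs: dict[tuple[str, str], set[int]] = {}
    for e in network.edges:
        signs.setdefault((e.regulator, e.target), set()).add(
            1 if e.sign == "+" else -1
        )
    try:
        paths = nx.all_simple_paths(g, s, t, cutoff=max_len)
    except nx.NodeNotFound:  # pragma: no cover
        return False
    for p in paths:
        prods = {1}
        for u, v in zip(p, p[1:]):
            prods = {a * b for a in prods for b in signs[(u, v)]}
        if want in prods:
            return True
    return False


# ---------------------------------------------------------------------------
# logic binary transitive reduction


def _drop_literal(expr: Expr, name: str) -> Expr | None:
    """Remove every literal of ``name``; ``None`` if nothing remains."""
    if isinstance(expr, Lit):
        return None if expr.name == name else expr
    kept = []
    for a in expr.args:
        r = _drop_literal(a, name)
        if r is not None:
            kept.append(r)
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return type(expr)(tuple(kept))


def lbtr_reduce(
    model: BooleanModel,
    network: RegulatoryNetwork,
    max_len: int = DEFAULT_MAX_PATH_LEN,
) -> tuple[RegulatoryNetwork, list[LogicEdge]]:
    """Logic binary transitive reduction.

    Removes a non-direct edge when a simple path of the same sign and
    composed causal logic exists without it; after each removal every
    implication that held on the model beforehand is re-verified by the
    forced-state oracle and the removal rolled back on any violation.
    Candidates are tried longest-spanning first (ties lexicographic) and
    the sweep repeats until a fixpoint.  Direct edges are never touched.
    The model is updated in place (removed regulators leave the rules).
    """
    import networkx as nx

    baseline = [
        e for e in network.edges
        if e.logic is not LogicLabel.UNKNOWN and _holds(model, e)
    ]
    removed: list[LogicEdge] = []
    changed = True
    while changed:
        changed = False
        candidates = [
            e for e in network.edges
            if e.directness is not Directness.DIRECT
            and e.logic is not LogicLabel.UNKNOWN
        ]

        def span(e: LogicEdge) -> int:
            g = network.to_networkx()
            if g.has_edge(e.regulator, e.target):
                g.remove_edge(e.regulator, e.target)
            try:
                return nx.shortest_path_length(g, e.regulator, e.target)
            except (nx.NetworkXNoPath, nx.NodeNotFound):
                return 0

        candidates.sort(key=lambda e: (-span(e), e.key))
        for e in candidates:
            trial = network.copy()
            trial.remove_edge(e)
            paths = find_supporting_paths(
                trial, e.regulator, e.target, e.logic, max_len
            )
            if not any(len(p.path) > 2 for p in paths):
                continue
            fn = model.functions.get(e.target)
            new_expr = (
                _drop_literal(fn.expression, e.regulator) if fn else None
            )
            if fn is not None and new_expr is None:
                continue  # sole regulator; removal would orphan the rule
            saved_fn = fn
            if fn is not None:
                model.set_function(
                    BooleanFunction(e.target, canonicalize(new_expr))
                )
            if all(_holds(model, b) for b in baseline if b.key != e.key):
                network.remove_edge(e)
                removed.append(e)
                baseline = [b for b in baseline if b.key != e.key]
                changed = True
            else:
                if saved_fn is not None:
                    model.set_function(saved_fn)
    return network, removed


def suggest_mediators(
    action: IntegrationAction,
    network: RegulatoryNetwork,
    max_len: int = DEFAULT_MAX_PATH_LEN,
) -> list[PathImplication]:
    """Mediator hypotheses for a resolved indirect relationship.

    For a relationship realised by existing paths, returns those
    supporting paths (shortest first); for an anchor-completed path,
    returns the completed path.  Other decisions yield no hypotheses.
    """
    e = action.relationship
    if action.decision == "no_edge_path_exists":
        if e.logic is LogicLabel.UNKNOWN:
            return []
        return find_supporting_paths(
            network, e.regulator, e.target, e.logic, max_len
        )
    if action.decision == "edge_to_upstream_regulator":
        return [action.evidence_path] if action.evidence_path else []
    return []
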