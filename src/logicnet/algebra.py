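"""The causal-logic calculus on models and networks.

Two complementary oracles decide whether a regulator's sustained state
forces a target's state "regardless of the state of other regulators":

* :func:`ldoi` — the logical domain of influence, a three-valued
  propagation fixpoint on a Boolean model.  Clamping a node and reading
  off the forced states decides implications *semantically*, including
  ones mediated by subgraphs and feedback.
* :func:`path_implication` / :func:`find_supporting_paths` — the
  *syntactic* route: composing edge labels along simple paths.

A supporting path of label L from R to T guarantees the model-level
implication (soundness); the converse does not hold, which is exactly why
the integration step consults the semantic oracle first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .expressions import forced_value
from .labels import LogicLabel, compose_pair_sets, label_from_pairs
from .model import BooleanModel, LogicEdge, ModelError, RegulatoryNetwork

__all__ = [
    "TernaryState",
    "PathImplication",
    "ldoi",
    "check_implication",
    "path_implication",
    "find_supporting_paths",
]


@dataclass
class TernaryState:
    """node → {0, 1, None(unknown)}, with externally clamped nodes fixed."""

    assignment: dict[str, int | None]
    clamped: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for c in self.clamped:
            if self.assignment.get(c) is None:
                raise ModelError(f"clamped node {c!r} has no value")

    def __getitem__(self, node: str) -> int | None:
        return self.assignment.get(node)

    def forced_nodes(self) -> dict[str, int]:
        return {k: v for k, v in sorted(self.assignment.items()) if v is not None}


def ldoi(model: BooleanModel, clamp: Mapping[str, int]) -> TernaryState:
    """Logical domain of influence of a clamp: the unique least fixpoint of
    three-valued propagation.

    A node becomes forced to v when its rule evaluates to v under *every*
    completion of its currently-unknown regulators; clamped nodes keep
    their clamped value regardless of their own rules.  Monotone: values
    are only ever added, never retracted, so the result is independent of
    propagation order.
    """
    if not clamp:
        raise ModelError("clamp must assign at least one node")
    nodes = model.nodes
    for n, v in clamp.items():
        if n not in nodes:
            raise ModelError(f"clamp on unknown node {n!r}")
        if v not in (0, 1):
            raise ModelError(f"clamp value for {n!r} must be 0 or 1")
    state: dict[str, int | None] = {n: None for n in nodes}
    state.update({n: int(v) for n, v in clamp.items()})
    clamped = frozenset(clamp)

    changed = True
    while changed:
        changed = False
        for node in sorted(model.functions):
            if node in clamped or state[node] is not None:
                continue
            v = forced_value(model.functions[node].expression, state)
            if v is not None:
                state[node] = v
                changed = True
    return TernaryState(state, clamped)


def check_implication(
    model: BooleanModel, regulator: str, logic: LogicLabel, target: str
) -> bool:
    """Does the model realise the claimed implication of R on T?

    ``sufficient`` holds iff clamping R = ON forces T = ON in the LDOI;
    the other labels follow the same trigger/forced pattern, and the
    sufficient-and-necessary labels require both constituent checks.
    """
    if logic is LogicLabel.UNKNOWN:
        raise ModelError("cannot check an unknown logic label")
    nodes = model.nodes
    for n in (regulator, target):
        if n not in nodes:
            raise ModelError(f"node {n!r} not in model")
    for trigger, forced in logic.pairs:
        state = ldoi(model, {regulator: trigger})
        if state[target] != forced:
            return False
    return True


@dataclass(frozen=True)
class PathImplication:
    """A simple path together with the label its edges compose to."""

    path: tuple[str, ...]
    composed: LogicLabel | None

    def mediators(self) -> tuple[str, ...]:
        return self.path[1:-1]

    def __str__(self) -> str:
        lab = self.composed.value if self.composed else "none"
        return " -> ".join(self.path) + f"  [{lab}]"


def _edge_pairs(network: RegulatoryNetwork, u: str, v: str) -> frozenset:
    """Union of implication pairs over all (parallel-sign) edges u→v."""
    pairs: set[tuple[int, int]] = set()
    for e in network.edges_between(u, v):
        pairs.update(e.logic.pairs)
    return frozenset(pairs)


def path_implication(
    network: RegulatoryNetwork, path: Sequence[str]
) -> LogicLabel | None:
    """Left fold of implication composition along a path's edges.

    Returns ``None`` as soon as no implication survives a step (e.g. a
    sufficient edge followed by a necessary edge, or any edge with no
    logic label).
    """
    if len(path) < 2:
        raise ModelError("a path needs at least one edge")
    for u, v in zip(path, path[1:]):
        if not network.has_edge(u, v):
            raise ModelError(f"no edge {u!r} -> {v!r} in network")
    acc = _edge_pairs(network, path[0], path[1])
    for u, v in zip(path[1:], path[2:]):
        acc = compose_pair_sets(acc, _edge_pairs(network, u, v))
        if not acc:
            return None
    return label_from_pairs(acc)


DEFAULT_MAX_PATH_LEN = 10  # signalling-network diameters are small


def find_supporting_paths(
    network: RegulatoryNetwork,
    source: str,
    target: str,
    logic: LogicLabel,
    max_len: int = DEFAULT_MAX_PATH_LEN,
) -> list[PathImplication]:
    """All simple paths of length ≤ max_len whose composed label matches.

    A path "matches" when its composed implication pairs include every
    pair the requested label asserts (so a sufficient-and-necessary chain
    supports a plain sufficient request).  Trivial self-paths are
    excluded.  Sorted by length, then lexicographically.
    """
    if max_len < 1:
        raise ModelError("max_len must be >= 1")
    if logic is LogicLabel.UNKNOWN:
        raise ModelError("cannot search for an unknown logic label")
    if source == target:
        return []
    if source not in network.nodes or target not in network.nodes:
        return []
    import networkx as nx

    g = network.to_networkx()
    want = frozenset(logic.pairs)
    out: list[PathImplication] = []
    for p in nx.all_simple_paths(g, source, target, cutoff=max_len):
        acc = _edge_pairs(network, p[0], p[1])
        for u, v in zip(p[1:], p[2:]):
            acc = compose_pair_sets(acc, _edge_pairs(network, u, v))
            if not acc:
                break
        if want <= acc:
            out.append(PathImplication(tuple(p), label_from_pairs(acc & want) or logic))
    out.sort(key=lambda pi: (len(pi.path), pi.path))
    return out
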