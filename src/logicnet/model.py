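"""Domain containers: labelled edges, networks, Boolean models."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Mapping

from .expressions import (
    Expr,
    Lit,
    canonicalize,
    essential_regulators,
    parse_expression,
    support,
)
from .labels import LogicLabel

__all__ = [
    "Directness",
    "Confidence",
    "LogicEdge",
    "RegulatoryNetwork",
    "BooleanFunction",
    "BooleanModel",
    "PartialTruthTable",
    "ModelError",
]


class ModelError(ValueError):
    pass


class Directness(str, Enum):
    DIRECT = "direct"
    #: indirect, but unlikely to share mediators with other relationships —
    #: represented as an edge from the start
    INDIRECT_INDEPENDENT = "indirect_independent"
    #: indirect and likely mediator-sharing — handled by path/subgraph logic
    INDIRECT_SHARED = "indirect_shared"


class Confidence(str, Enum):
    HIGH = "high"
    LOW = "low"  # the asterisked, lower-confidence implications


@dataclass(frozen=True)
class LogicEdge:
    """A signed regulator→target relation with a causal-logic label."""

    regulator: str
    target: str
    sign: str  # '+' or '-'
    logic: LogicLabel = LogicLabel.UNKNOWN
    directness: Directness = Directness.DIRECT
    confidence: Confidence = Confidence.HIGH
    provenance: str = ""
    #: Declared biological support for a pathway via this anchor node
    #: (used when completing a path instead of adding an independent edge).
    support_anchor: str | None = None
    self_loop_ok: bool = False

    def __post_init__(self) -> None:
        if self.sign not in {"+", "-"}:
            raise ModelError(f"sign must be '+' or '-', got {self.sign!r}")
        if self.logic is not LogicLabel.UNKNOWN and self.logic.sign != self.sign:
            raise ModelError(
                f"edge {self.regulator}->{self.target}: sign {self.sign!r} "
                f"contradicts logic {self.logic.value!r}"
            )
        if self.regulator == self.target and not self.self_loop_ok:
            raise ModelError(
                f"self-loop on {self.regulator!r} must be explicitly flagged"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.regulator, self.target, self.sign)

    def __str__(self) -> str:
        mark = "*" if self.confidence is Confidence.LOW else ""
        return (
            f"{self.regulator} -[{self.logic.value}{mark}, "
            f"{self.directness.value}]-> {self.target}"
        )


class RegulatoryNetwork:
    """Node set plus labelled edges; at most one edge per (reg, target, sign)."""

    def __init__(
        self, nodes: Iterable[str] = (), edges: Iterable[LogicEdge] = ()
    ) -> None:
        self.nodes: set[str] = set(nodes)
        self._edges: dict[tuple[str, str, str], LogicEdge] = {}
        for e in edges:
            self.add_edge(e)

    @property
    def edges(self) -> list[LogicEdge]:
        return [self._edges[k] for k in sorted(self._edges)]

    def add_edge(self, edge: LogicEdge) -> None:
        if edge.key in self._edges:
            raise ModelError(f"duplicate edge {edge.key}")
        self._edges[edge.key] = edge
        self.nodes.add(edge.regulator)
        self.nodes.add(edge.target)

    def remove_edge(self, edge: LogicEdge) -> None:
        del self._edges[edge.key]

    def has_edge(self, regulator: str, target: str, sign: str | None = None) -> bool:
        if sign is not None:
            return (regulator, target, sign) in self._edges
        return any(k[:2] == (regulator, target) for k in self._edges)

    def edges_between(self, regulator: str, target: str) -> list[LogicEdge]:
        return [
            self._edges[k] for k in sorted(self._edges) if k[:2] == (regulator, target)
        ]

    def in_edges(self, target: str) -> list[LogicEdge]:
        return [e for e in self.edges if e.target == target]

    def out_edges(self, regulator: str) -> list[LogicEdge]:
        return [e for e in self.edges if e.regulator == regulator]

    def regulators_of(self, target: str) -> list[str]:
        return sorted({e.regulator for e in self.in_edges(target)})

    def source_nodes(self) -> set[str]:
        regulated = {e.target for e in self.edges}
        return self.nodes - regulated

    def copy(self) -> "RegulatoryNetwork":
        return RegulatoryNetwork(self.nodes, self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for e in self.edges:
            g.add_edge(e.regulator, e.target)
        return g

    def has_path(self, source: str, target: str) -> bool:
        """Directed reachability (any sign/logic)."""
        if source not in self.nodes or target not in self.nodes:
            return False
        succ: dict[str, set[str]] = {}
        for e in self.edges:
            succ.setdefault(e.regulator, set()).add(e.target)
        seen = {source}
        stack = [source]
        while stack:
            u = stack.pop()
            for v in succ.get(u, ()):
                if v == target:
                    return True
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return False

    def __len__(self) -> int:
        return len(self._edges)


@dataclass(frozen=True)
class BooleanFunction:
    """An update rule ``target* = expression`` (the asterisk denotes the
    next-timestep state of the target)."""

    target: str
    expression: Expr

    @classmethod
    def parse(cls, target: str, text: str) -> "BooleanFunction":
        return cls(target, parse_expression(text))

    @property
    def regulators(self) -> tuple[str, ...]:
        return support(self.expression)

    def validate_essential(self) -> None:
        roles = essential_regulators(self.expression)
        redundant = [v for v in self.regulators if v not in roles]
        ambiguous = [v for v, r in roles.items() if r == "ambiguous"]
        if redundant or ambiguous:
            raise ModelError(
                f"rule for {self.target}: redundant regulators {redundant}, "
                f"ambiguous regulators {ambiguous}"
            )

    def __str__(self) -> str:
        return f"{self.target}* = {canonicalize(self.expression)}"


class BooleanModel:
    """Mapping node → update rule; source nodes carry no rule."""

    def __init__(
        self,
        functions: Mapping[str, BooleanFunction] | Iterable[BooleanFunction] = (),
        sources: Iterable[str] = (),
    ) -> None:
        if isinstance(functions, Mapping):
            fns = list(functions.values())
        else:
            fns = list(functions)
        self.functions: dict[str, BooleanFunction] = {}
        for f in fns:
            if f.target in self.functions:
                raise ModelError(f"two rules for node {f.target!r}")
            self.functions[f.target] = f
        self.sources: set[str] = set(sources)
        overlap = self.sources & set(self.functions)
        if overlap:
            raise ModelError(f"source nodes with rules: {sorted(overlap)}")

    @property
    def nodes(self) -> set[str]:
        names = set(self.sources) | set(self.functions)
        for f in self.functions.values():
            names.update(f.regulators)
        return names

    def set_function(self, f: BooleanFunction) -> None:
        self.functions[f.target] = f
        self.sources.discard(f.target)

    def remove_function(self, node: str) -> None:
        self.functions.pop(node, None)

    def validate(self) -> None:
        nodes = self.nodes
        for f in self.functions.values():
            for r in f.regulators:
                if r not in nodes:  # pragma: no cover - nodes includes supports
                    raise ModelError(f"unbound literal {r!r} in rule for {f.target}")
            f.validate_essential()

    def implied_edges(self) -> set[tuple[str, str]]:
        out = set()
        for f in self.functions.values():
            for r in f.regulators:
                out.add((r, f.target))
        return out

    def copy(self) -> "BooleanModel":
        return BooleanModel(dict(self.functions), set(self.sources))

    def __str__(self) -> str:
        lines = [str(self.functions[k]) for k in sorted(self.functions)]
        lines += [f"{s}* = {s}  (source)" for s in sorted(self.sources)]
        return "\n".join(lines)


@dataclass
class PartialTruthTable:
    """Observed target values for (possibly incomplete) regulator contexts.

    Each row is ``(assignment, value)``; regulators missing from the
    assignment are unknown, and the row asserts the value for *every*
    completion of the unknowns (the canalizing reading of a perturbation
    experiment).
    """

    target: str
    rows: list[tuple[dict[str, int], int]] = field(default_factory=list)

    def add_row(self, assignment: Mapping[str, int], value: int) -> None:
        asg = {k: int(v) for k, v in assignment.items()}
        for prev_asg, prev_val in self.rows:
            if prev_asg == asg and prev_val != value:
                raise ModelError(
                    f"contradictory rows for {self.target}: {asg} -> "
                    f"{prev_val} vs {value}"
                )
        self.rows.append((asg, int(value)))

    def variables(self) -> tuple[str, ...]:
        names: set[str] = set()
        for asg, _ in self.rows:
            names.update(asg)
        return tuple(sorted(names))
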