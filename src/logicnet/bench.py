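"""Synthetic ground-truth models and the rule-recovery benchmark.

A reusable replica of the re-inference experiment: draw a random Boolean
model whose rules lie in the family the causal-logic grammar can express,
read per-edge logical observations straight off the rules, optionally
corrupt them the way real inputs are incomplete (redundant indirect
statements, two-node paths replaced by indirect statements, uniformly
dropped statements), run the inference pipeline, and score how many rules
are re-discovered up to semantic equality.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .expressions import And, Expr, Lit, Or, canonicalize
from .labels import LogicLabel, compose_pair_sets, label_from_pairs
from .model import (
    BooleanFunction,
    BooleanModel,
    Confidence,
    Directness,
    ModelError,
)
from .statements import CausalStatement
from .expressions import semantic_equal

__all__ = [
    "GeneratorConfig",
    "CorruptionConfig",
    "RecoveryScore",
    "generate_model",
    "derive_statements",
    "corrupt_statements",
    "score_recovery",
    "run_recovery_experiment",
]


@dataclass(frozen=True)
class GeneratorConfig:
    n_nodes: int = 20
    max_in_degree: int = 3
    #: single_layer: pure OR / pure AND / single literal — exactly the
    #: forms whose per-edge labels determine the rule, so full input makes
    #: perfect recovery the correct oracle.  two_layer adds one nested
    #: group whose members carry sign-only observations (the method's
    #: documented limit; recovery < 1 expected).
    function_family: str = "single_layer"
    negation_probability: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ModelError("n_nodes must be >= 2")
        if self.max_in_degree < 1:
            raise ModelError("max_in_degree must be >= 1")
        if not 0.0 <= self.negation_probability <= 1.0:
            raise ModelError("negation_probability must be in [0, 1]")
        if self.function_family not in {"single_layer", "two_layer"}:
            raise ModelError(f"unknown family {self.function_family!r}")


@dataclass(frozen=True)
class CorruptionConfig:
    drop_fraction: float = 0.0
    #: number of two-node paths replaced by an indirect statement (one
    #: constituent statement deleted at random; the mediator is recorded
    #: as the declared pathway-support anchor, as a curator would know it)
    indirection_count: int = 0
    #: indirect statements duplicating an existing same-logic two-node
    #: path (redundant; the reduction step should eliminate them)
    add_redundant_indirect: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop_fraction <= 1.0:
            raise ModelError("drop_fraction must be in [0, 1]")
        if self.indirection_count < 0 or self.add_redundant_indirect < 0:
            raise ModelError("corruption counts must be >= 0")


def _node_names(n: int) -> list[str]:
    width = max(2, len(str(n - 1)))
    return [f"n{i:0{width}d}" for i in range(n)]


def generate_model(cfg: GeneratorConfig) -> BooleanModel:
    """Random connected regulatory network with family-restricted rules.

    Nodes are ordered; the first ~15% (at least one) are sources and every
    later node draws 1..max_in_degree regulators from strictly earlier
    nodes, so the graph is acyclic and every node traces back to a
    source.  Resamples (from the same deterministic stream) until weakly
    connected.  Deterministic under a fixed seed.
    """
    rng = random.Random(cfg.seed)
    names = _node_names(cfg.n_nodes)
    n_sources = max(1, round(0.15 * cfg.n_nodes))
    for _attempt in range(100):
        functions: list[BooleanFunction] = []
        edges: set[tuple[str, str]] = set()
        for i in range(n_sources, cfg.n_nodes):
            k = rng.randint(1, min(cfg.max_in_degree, i))
            regs = sorted(rng.sample(names[:i], k))
            for r in regs:
                edges.add((r, names[i]))
            functions.append(
                BooleanFunction(names[i], _random_expression(rng, regs, cfg))
            )
        if _weakly_connected(names, edges):
            model = BooleanModel(functions, sources=names[:n_sources])
            model.validate()
            return model
    raise ModelError(
        "could not draw a connected network under the degree constraints"
    )


def _weakly_connected(names: Sequence[str], edges: set[tuple[str, str]]) -> bool:
    adj: dict[str, set[str]] = {n: set() for n in names}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = {names[0]}
    stack = [names[0]]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == len(names)


def _random_expression(
    rng: random.Random, regs: Sequence[str], cfg: GeneratorConfig
) -> Expr:
    lits = [Lit(r, rng.random() < cfg.negation_probability) for r in regs]
    if len(lits) == 1:
        return lits[0]
    two_layer = cfg.function_family == "two_layer" and len(lits) >= 3
    outer, inner = (Or, And) if rng.random() < 0.5 else (And, Or)
    if not two_layer:
        return canonicalize(outer(tuple(lits)))
    g = rng.randint(2, len(lits) - 1)
    group = rng.sample(range(len(lits)), g)
    group_set = set(group)
    outside = [l for i, l in enumerate(lits) if i not in group_set]
    block = inner(tuple(lits[i] for i in sorted(group_set)))
    return canonicalize(outer(tuple(outside + [block])))


# ---------------------------------------------------------------------------
# observations


def _literal_label(lit: Lit, context: str) -> LogicLabel:
    """Label a literal carries given its position in the rule.

    In an OR-rule, a plain literal is sufficient and a negated one
    necessary-inhibitory; in an AND-rule, plain is necessary and negated
    sufficient-inhibitory; a sole literal is sufficient-and-necessary
    (inhibitory when negated).
    """
    if context == "or":
        return (
            LogicLabel.NECESSARY_INHIBITORY if lit.negated
            else LogicLabel.SUFFICIENT
        )
    if context == "and":
        return (
            LogicLabel.SUFFICIENT_INHIBITORY if lit.negated
            else LogicLabel.NECESSARY
        )
    return (
        LogicLabel.SUFFICIENT_AND_NECESSARY_INHIBITORY if lit.negated
        else LogicLabel.SUFFICIENT_AND_NECESSARY
    )


def derive_statements(model: BooleanModel) -> list[CausalStatement]:
    """Per-edge logical observations read off the rules.

    One direct pair statement per (regulator, target) edge; members of a
    nested group are observed with their sign only (they are neither
    independently sufficient nor independently necessary).
    """
    out: list[CausalStatement] = []
    for target in sorted(model.functions):
        expr = canonicalize(model.functions[target].expression)
        items: list[tuple[Lit, LogicLabel]] = []
        if isinstance(expr, Lit):
            items.append((expr, _literal_label(expr, "sole")))
        elif isinstance(expr, (And, Or)):
            context = "or" if isinstance(expr, Or) else "and"
            for arg in expr.args:
                if isinstance(arg, Lit):
                    items.append((arg, _literal_label(arg, context)))
                else:  # nested group: sign-only observations
                    for lit in arg.args:
                        if not isinstance(lit, Lit):
                            raise ModelError(
                                f"rule for {target} is outside the "
                                "representable family"
                            )
                        items.append((lit, LogicLabel.UNKNOWN))
        else:  # pragma: no cover
            raise ModelError(f"unsupported rule shape for {target}")
        for lit, label in sorted(items, key=lambda il: il[0].name):
            out.append(
                CausalStatement(
                    kind="pair",
                    regulator=lit.name,
                    target=target,
                    sign="-" if lit.negated else "+",
                    logic=label,
                    directness=Directness.DIRECT,
                    confidence=Confidence.HIGH,
                    evidence="other",
                )
            )
    return out


def _composable_paths(
    stmts: Sequence[CausalStatement],
) -> list[tuple[CausalStatement, CausalStatement, LogicLabel]]:
    """Two-node paths A→M→T whose labels compose to a nameable label.

    Pairs already related by a statement of their own are excluded: the
    emulated modifications introduce indirect relationships between nodes
    that are not otherwise connected.
    """
    by_reg: dict[str, list[CausalStatement]] = {}
    related = {(s.regulator, s.target) for s in stmts}
    for s in stmts:
        if s.kind == "pair" and s.logic is not LogicLabel.UNKNOWN:
            by_reg.setdefault(s.regulator, []).append(s)
    out = []
    for first in stmts:
        if first.kind != "pair" or first.logic is LogicLabel.UNKNOWN:
            continue
        for second in by_reg.get(first.target, []):
            if second.target == first.regulator:
                continue  # would be a self-relationship
            if (first.regulator, second.target) in related:
                continue  # already directly related
            pairs = compose_pair_sets(
                frozenset(first.logic.pairs), frozenset(second.logic.pairs)
            )
            label = label_from_pairs(pairs)
            if label is not None:
                out.append((first, second, label))
    out.sort(key=lambda fst: (fst[0].regulator, fst[0].target, fst[1].target))
    return out


def corrupt_statements(
    stmts: Sequence[CausalStatement],
    model: BooleanModel,
    cfg: CorruptionConfig,
) -> tuple[list[CausalStatement], dict]:
    """Apply the configured corruptions; returns (statements, manifest).

    Order: redundant-indirect additions, path-to-indirect replacements,
    uniform statement drops — all driven by the config seed, with every
    change recorded in the manifest.
    """
    rng = random.Random(cfg.seed)
    stmts = list(stmts)
    manifest: dict = {"redundant_added": [], "replacements": [], "dropped": []}

    paths = _composable_paths(stmts)
    need = cfg.add_redundant_indirect + cfg.indirection_count
    if need > len(paths):
        raise ModelError(
            f"requested {need} path corruptions but only {len(paths)} "
            "composable two-node paths exist"
        )
    chosen = rng.sample(paths, need) if need else []
    redundant = chosen[: cfg.add_redundant_indirect]
    replacements = chosen[cfg.add_redundant_indirect:]

    for first, second, label in redundant:
        stmt = CausalStatement(
            kind="pair",
            regulator=first.regulator,
            target=second.target,
            sign=label.sign,
            logic=label,
            directness=Directness.INDIRECT_INDEPENDENT,
            evidence="other",
        )
        stmts.append(stmt)
        manifest["redundant_added"].append(
            {
                "regulator": first.regulator,
                "mediator": first.target,
                "target": second.target,
                "logic": label.value,
            }
        )

    for first, second, label in replacements:
        victim = rng.choice([first, second])
        if victim not in stmts:
            continue  # already consumed by an overlapping replacement
        stmts.remove(victim)
        indirect = CausalStatement(
            kind="pair",
            regulator=first.regulator,
            target=second.target,
            sign=label.sign,
            logic=label,
            directness=Directness.INDIRECT_SHARED,
            evidence="other",
            support=first.target,  # the mediator, as the curator knows it
        )
        stmts.append(indirect)
        manifest["replacements"].append(
            {
                "regulator": first.regulator,
                "mediator": first.target,
                "target": second.target,
                "logic": label.value,
                "deleted": f"{victim.regulator}->{victim.target}",
            }
        )

    if cfg.drop_fraction > 0:
        n_drop = round(cfg.drop_fraction * len(stmts))
        dropped = rng.sample(stmts, n_drop)
        for d in dropped:
            stmts.remove(d)
            manifest["dropped"].append(f"{d.regulator}->{d.target}")
    return stmts, manifest


@dataclass
class RecoveryScore:
    n_nodes: int
    n_correct: int
    verdicts: dict[str, bool] = field(default_factory=dict)

    @property
    def fraction(self) -> float:
        return self.n_correct / self.n_nodes if self.n_nodes else 1.0


def score_recovery(truth: BooleanModel, inferred: BooleanModel) -> RecoveryScore:
    """Per-node semantic comparison of inferred vs ground-truth rules.

    Source nodes of the truth are excluded from the denominator unless
    the inference assigned them a rule (then they count, as incorrect);
    nodes the inference lost count as incorrect.
    """
    scored = sorted(
        set(truth.functions)
        | {s for s in truth.sources if s in inferred.functions}
    )
    verdicts: dict[str, bool] = {}
    for node in scored:
        t = truth.functions.get(node)
        f = inferred.functions.get(node)
        if t is None or f is None:
            verdicts[node] = False
        else:
            verdicts[node] = semantic_equal(t.expression, f.expression)
    return RecoveryScore(
        n_nodes=len(scored),
        n_correct=sum(verdicts.values()),
        verdicts=verdicts,
    )


def run_recovery_experiment(
    gen_cfg: GeneratorConfig,
    cor_cfg: CorruptionConfig | None = None,
    template: str = "sufficient_dominant",
) -> tuple[RecoveryScore, "object"]:
    """generate → derive → corrupt → infer → score, end to end."""
    from .pipeline import infer_from_statements

    truth = generate_model(gen_cfg)
    stmts = derive_statements(truth)
    if cor_cfg is not None:
        stmts, _ = corrupt_statements(stmts, truth, cor_cfg)
    result = infer_from_statements(stmts, template=template)
    return score_recovery(truth, result.model), result
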