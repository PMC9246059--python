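"""Per-target rule assembly: compatibility, templates, manual resolution.

The labels of the regulators incident on a target either all force the
target to the same value — in which case a single OR-rule (forced-to-1
labels) or AND-rule (forced-to-0 labels) preserves every one of them — or
they conflict.  Conflicts are resolved by the dominant-regulators method
(two templates that group the non-dominant side into a single block), or
manually from experiment context / partial truth tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .expressions import (
    And,
    Expr,
    Lit,
    Or,
    canonicalize,
    count_literals,
    evaluate,
    expression_from_truth_table,
)
from .labels import LogicLabel
from .model import (
    BooleanFunction,
    Confidence,
    Directness,
    LogicEdge,
    ModelError,
    PartialTruthTable,
)

__all__ = [
    "check_compatibility",
    "assemble_function",
    "AssemblyOutcome",
    "Resolution",
    "resolve_with_context",
    "resolve_with_truth_table",
]

_SANDN = {
    LogicLabel.SUFFICIENT_AND_NECESSARY,
    LogicLabel.SUFFICIENT_AND_NECESSARY_INHIBITORY,
}


def _forced(label: LogicLabel) -> int:
    """The target value a basic label forces (1: OR-family, 0: AND-family)."""
    (_, f), = label.pairs
    return f


def check_compatibility(
    labels: Iterable[LogicLabel],
) -> tuple[bool, list[tuple[LogicLabel, LogicLabel]]]:
    """Pairwise compatibility of the labels incident on one target.

    Two basic labels are compatible iff they force the target to the same
    value; a sufficient-and-necessary label is compatible only as the sole
    regulator.  Returns (compatible, list of violating pairs).
    """
    labs = list(labels)
    if not labs:
        raise ModelError("check_compatibility needs at least one label")
    if any(l is LogicLabel.UNKNOWN for l in labs):
        raise ModelError("resolve unknown labels before checking compatibility")
    conflicts: list[tuple[LogicLabel, LogicLabel]] = []
    for a, b in itertools.combinations(labs, 2):
        if a in _SANDN or b in _SANDN:
            conflicts.append((a, b))
        elif _forced(a) != _forced(b):
            conflicts.append((a, b))
    return (not conflicts, conflicts)


@dataclass
class AssemblyOutcome:
    target: str
    status: str  # compatible | resolved_template1 | resolved_template2 |
    #              resolved_manual | unresolved
    functions: list[BooleanFunction] = field(default_factory=list)
    conflicts: list[tuple[str, str]] = field(default_factory=list)
    #: regulators whose individual label a template weakened into a group
    grouped: list[str] = field(default_factory=list)
    #: regulators whose low-confidence label was demoted to sign-only
    demoted: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def function(self) -> BooleanFunction | None:
        return self.functions[0] if self.functions else None


def _merge_parallel(edges: Sequence[LogicEdge]) -> tuple[dict[str, dict], list[str]]:
    """Merge duplicate statements about the same regulator.

    Consistent duplicates merge to the strictest label (sufficient +
    necessary from the same regulator means sufficient-and-necessary);
    irreconcilable ones (opposite signs, or implication pairs that name no
    label) are flagged for manual resolution.
    """
    merged: dict[str, dict] = {}
    flags: list[str] = []
    for e in sorted(edges, key=lambda e: e.key):
        info = merged.setdefault(
            e.regulator,
            {"pairs": set(), "signs": set(), "confidence": Confidence.HIGH,
             "edges": []},
        )
        info["pairs"].update(e.logic.pairs)
        info["signs"].add(e.sign)
        info["edges"].append(e)
        if e.confidence is Confidence.LOW:
            info["confidence"] = Confidence.LOW
    for reg, info in merged.items():
        if len(info["signs"]) > 1:
            flags.append(f"regulator {reg}: contradictory signs, kept first sign")
            first = info["edges"][0]
            info["signs"] = {first.sign}
            info["pairs"] = set(first.logic.pairs)
        from .labels import label_from_pairs

        label = label_from_pairs(info["pairs"]) if info["pairs"] else None
        if info["pairs"] and label is None:
            flags.append(
                f"regulator {reg}: duplicate statements with irreconcilable "
                "labels, demoted to sign-only"
            )
            info["pairs"] = set()
            label = None
        info["label"] = label if label is not None else LogicLabel.UNKNOWN
        info["sign"] = next(iter(info["signs"]))
    return merged, flags


def _lit(reg: str, negated: bool) -> Lit:
    return Lit(reg, negated)


def _join(op, parts: list[Expr]) -> Expr:
    if len(parts) == 1:
        return parts[0]
    return canonicalize(op(tuple(parts)))


def assemble_function(
    target: str,
    edges: Sequence[LogicEdge],
    template: str = "sufficient_dominant",
) -> AssemblyOutcome:
    """Build the update rule(s) for one target from its labelled edges.

    ``template`` is ``sufficient_dominant`` (group the necessary side),
    ``necessary_dominant`` (group the sufficient side) or ``both`` (return
    both candidates, sufficient-dominant first).  Compatible label sets
    need no template; sign-only (unknown-logic) regulators join the
    resolved side with its operator, keeping their sign as the literal's
    polarity.
    """
    if template not in {"sufficient_dominant", "necessary_dominant", "both"}:
        raise ModelError(f"unknown template {template!r}")
    edges = [e for e in edges if e.target == target]
    if not edges:
        raise ModelError(f"no edges for target {target!r}")
    merged, flags = _merge_parallel(edges)
    outcome = AssemblyOutcome(target=target, status="compatible", notes=flags)

    regs = sorted(merged)
    # single regulator: promoting -> T* = R, inhibiting -> T* = not R
    if len(regs) == 1:
        reg = regs[0]
        expr = _lit(reg, merged[reg]["sign"] == "-")
        outcome.functions = [BooleanFunction(target, expr)]
        return outcome

    sandn = [r for r in regs if merged[r]["label"] in _SANDN]
    if sandn:
        compatible, conflicts = check_compatibility(
            [merged[r]["label"] for r in regs
             if merged[r]["label"] is not LogicLabel.UNKNOWN]
        )
        outcome.status = "unresolved"
        outcome.conflicts = [(a.value, b.value) for a, b in conflicts]
        outcome.notes.append(
            f"sufficient-and-necessary regulator(s) {sandn} cannot have "
            "co-regulators; needs manual re-evaluation"
        )
        return outcome

    known = {r: merged[r]["label"] for r in regs
             if merged[r]["label"] is not LogicLabel.UNKNOWN}
    unknown = [r for r in regs if r not in known]

    def conflict_pairs(labels: Mapping[str, LogicLabel]):
        out = []
        for a, b in itertools.combinations(sorted(labels), 2):
            if _forced(labels[a]) != _forced(labels[b]):
                out.append((a, b))
        return out

    conflicts = conflict_pairs(known)

    # low-confidence labels lose ties against high-confidence labels
    if conflicts:
        conf = {r: merged[r]["confidence"] for r in known}
        losers = {
            r
            for a, b in conflicts
            for r, other in ((a, b), (b, a))
            if conf[r] is Confidence.LOW and conf[other] is Confidence.HIGH
        }
        if losers:
            trial = {r: l for r, l in known.items() if r not in losers}
            if not trial or not conflict_pairs(trial):
                for r in sorted(losers):
                    outcome.demoted.append(r)
                    outcome.notes.append(
                        f"low-confidence label of {r} demoted to sign-only to "
                        "resolve a conflict with high-confidence labels"
                    )
                known = trial
                unknown = [r for r in regs if r not in known]
                conflicts = []

    def or_literal(r: str) -> Lit:
        # forced-to-1 side: promoting regulators plain, inhibitory negated
        return _lit(r, merged[r]["sign"] == "-")

    def and_literal(r: str) -> Lit:
        # forced-to-0 side: promoting plain, inhibitory negated
        return _lit(r, merged[r]["sign"] == "-")

    or_side = [r for r in known if _forced(known[r]) == 1]
    and_side = [r for r in known if _forced(known[r]) == 0]

    if not conflicts:
        # compatible: one side empty (or both, if all labels are unknown)
        if or_side or (not and_side and all(
            merged[r]["sign"] == "+" for r in unknown
        )):
            parts = [or_literal(r) for r in sorted(set(or_side) | set(unknown))]
            expr = _join(Or, parts)
        elif and_side:
            parts = [and_literal(r) for r in sorted(set(and_side) | set(unknown))]
            expr = _join(And, parts)
        else:
            # no known labels: OR the promoting, AND-in the negated inhibitory
            pos = [or_literal(r) for r in unknown if merged[r]["sign"] == "+"]
            neg = [and_literal(r) for r in unknown if merged[r]["sign"] == "-"]
            inner = [_join(Or, pos)] if pos else []
            expr = _join(And, inner + neg)
            outcome.notes.append(
                "no logic labels available; rule built from signs alone"
            )
        fn = BooleanFunction(target, canonicalize(expr))
        outcome.functions = [fn]
        return outcome

    # incompatible: dominant-regulators templates
    outcome.conflicts = [
        (known[a].value, known[b].value) for a, b in conflicts
    ]
    unknown_pos = [r for r in unknown if merged[r]["sign"] == "+"]
    unknown_neg = [r for r in unknown if merged[r]["sign"] == "-"]

    def template1() -> tuple[BooleanFunction, list[str]]:
        # sufficient regulators dominant; the necessary side becomes one
        # collectively-sufficient AND block
        group = sorted(set(and_side) | set(unknown_neg))
        parts = [or_literal(r) for r in sorted(set(or_side) | set(unknown_pos))]
        if group:
            parts.append(_join(And, [and_literal(r) for r in group]))
        return BooleanFunction(target, _join(Or, parts)), group

    def template2() -> tuple[BooleanFunction, list[str]]:
        # necessary regulators dominant; the sufficient side becomes one
        # collectively-necessary OR block
        group = sorted(set(or_side) | set(unknown_pos))
        parts = [and_literal(r) for r in sorted(set(and_side) | set(unknown_neg))]
        if group:
            parts.append(_join(Or, [or_literal(r) for r in group]))
        return BooleanFunction(target, _join(And, parts)), group

    if template == "sufficient_dominant":
        fn, group = template1()
        outcome.functions, outcome.grouped = [fn], group
        outcome.status = "resolved_template1"
    elif template == "necessary_dominant":
        fn, group = template2()
        outcome.functions, outcome.grouped = [fn], group
        outcome.status = "resolved_template2"
    else:
        f1, g1 = template1()
        f2, _ = template2()
        outcome.functions, outcome.grouped = [f1, f2], g1
        outcome.status = "resolved_template1"
        outcome.notes.append("both templates recorded; sufficient-dominant first")
    return outcome


# ---------------------------------------------------------------------------
# manual resolution: context knowledge and partial truth tables


@dataclass
class Resolution:
    function: BooleanFunction
    n_candidates: int
    ambiguous: bool = False
    notes: list[str] = field(default_factory=list)


_ENUM_LIMIT = 4  # 2^(2^4) = 65536 candidate tables; beyond that, no search


def _expand_keys(variables: Sequence[str], asg: Mapping[str, int]):
    free = [v for v in variables if v not in asg]
    for bits in itertools.product((0, 1), repeat=len(free)):
        full = dict(asg)
        full.update(zip(free, bits))
        yield tuple(full[v] for v in variables)


def _fill_cells(
    variables: Sequence[str],
    rows: Sequence[tuple[Mapping[str, int], int]],
    overridable: Sequence[tuple[Mapping[str, int], int]] = (),
) -> dict[tuple[int, ...], int]:
    """Pin truth-table cells from observation rows.

    ``rows`` are hard constraints (a contradiction raises); ``overridable``
    rows — universal claims of labels whose experiment context is unknown —
    apply only to cells the hard rows leave unspecified, which is exactly
    how a contexted observation weakens an apparently incompatible label.
    """
    cells: dict[tuple[int, ...], int] = {}
    for asg, val in rows:
        for key in _expand_keys(variables, asg):
            if cells.get(key, val) != val:
                raise ModelError(
                    f"contradictory observation rows at {dict(zip(variables, key))}"
                )
            cells[key] = val
    soft: dict[tuple[int, ...], int] = {}
    for asg, val in overridable:
        for key in _expand_keys(variables, asg):
            if key in cells:
                continue  # overridden by a contexted observation
            if soft.get(key, val) != val:
                raise ModelError(
                    "conflicting logic labels with no experiment context at "
                    f"{dict(zip(variables, key))}; supply context or a truth "
                    "table"
                )
            soft[key] = val
    cells.update(soft)
    return cells


def _unate_essential(table: dict, variables: Sequence[str],
                     signs: Mapping[str, str]) -> bool:
    for i, v in enumerate(variables):
        up = down = False
        for key in table:
            if key[i] == 0:
                other = key[:i] + (1,) + key[i + 1:]
                if table[other] > table[key]:
                    up = True
                elif table[other] < table[key]:
                    down = True
        if not (up or down):
            return False  # redundant regulator
        if up and down:
            return False  # ambiguous effect
        want = signs.get(v, "?")
        if want == "+" and down:
            return False
        if want == "-" and up:
            return False
    return True


def _search_functions(
    variables: Sequence[str],
    signs: Mapping[str, str],
    cells: Mapping[tuple[int, ...], int],
) -> list[dict]:
    """All unate, all-essential truth tables matching the pinned cells."""
    variables = list(variables)
    k = len(variables)
    if k > _ENUM_LIMIT:
        raise ModelError(
            f"cannot enumerate candidate rules over {k} regulators "
            f"(limit {_ENUM_LIMIT}); resolve with a template instead"
        )
    keys = list(itertools.product((0, 1), repeat=k))
    out = []
    for outputs in itertools.product((0, 1), repeat=len(keys)):
        table = dict(zip(keys, outputs))
        if all(table[key] == v for key, v in cells.items()) and \
                _unate_essential(table, variables, signs):
            out.append(table)
    return out


def _edge_rows(
    edges: Sequence[LogicEdge],
    context: Mapping[str, Mapping[str, int]] | None = None,
) -> list[tuple[dict[str, int], int]]:
    """Canalizing rows asserted by labelled edges.

    Without context a basic label asserts ``{R: trigger} -> forced`` for
    every completion of the co-regulators.  Context narrows the assertion
    to the co-regulator states assumed during the experiment behind that
    label, which is how apparently incompatible labels become jointly
    satisfiable.
    """
    context = context or {}
    rows = []
    for e in sorted(edges, key=lambda e: e.key):
        for trigger, forced in e.logic.pairs:
            asg = {e.regulator: trigger}
            for co, v in sorted(context.get(e.regulator, {}).items()):
                asg[co] = int(v)
            rows.append((asg, forced))
    return rows


def resolve_with_context(
    target: str,
    edges: Sequence[LogicEdge],
    context: Mapping[str, Mapping[str, int]],
    template: str = "sufficient_dominant",
) -> Resolution:
    """Resolve conflicting labels using knowledge of experiment contexts.

    ``context[R]`` gives the assumed ON/OFF states of R's co-regulators
    during the experiment that produced R's label.  Each label then
    asserts its forced value only for completions of that context, and
    the unique minimal rule consistent with all assertions (unate in every
    sign, no redundant regulator) is returned.  With an empty context and
    compatible labels this reduces to plain assembly.
    """
    edges = [e for e in edges if e.target == target]
    labels = [e.logic for e in edges if e.logic is not LogicLabel.UNKNOWN]
    if labels and not any(context.values() if context else ()):
        compatible, _ = check_compatibility(labels) if labels else (True, [])
        if compatible:
            outcome = assemble_function(target, edges, template)
            return Resolution(outcome.function, 1, notes=["no-op context"])
    merged, _ = _merge_parallel(edges)
    variables = sorted(merged)
    signs = {r: merged[r]["sign"] for r in variables}
    contexted = [e for e in edges if context.get(e.regulator)]
    uncontexted = [e for e in edges if not context.get(e.regulator)]
    hard = _edge_rows(contexted, context)
    soft = _edge_rows(uncontexted)
    cells = _fill_cells(variables, hard, soft)
    candidates = _search_functions(variables, signs, cells)
    if not candidates:
        raise ModelError(
            f"no rule for {target} is consistent with the context rows: "
            f"{hard + soft}"
        )
    return _pick(target, variables, candidates, edges, template)


def resolve_with_truth_table(
    target: str,
    table: PartialTruthTable,
    edges: Sequence[LogicEdge],
    template: str = "sufficient_dominant",
) -> Resolution:
    """Find the rule agreeing with an incomplete truth table and with every
    compatible logic label on the unspecified rows.

    Among the consistent candidates, prefers fewest literals (after
    minimisation), then the lexicographically first canonical form, and
    reports how many candidates existed.
    """
    edges = [e for e in edges if e.target == target]
    merged, _ = _merge_parallel(edges)
    variables = sorted(set(merged) | set(table.variables()))
    signs = {r: merged[r]["sign"] for r in merged}
    rows = list(table.rows) + _edge_rows(edges)
    candidates = _satisfying(variables, signs, rows)
    if not candidates:
        conflict = _minimal_conflict(variables, signs, rows)
        raise ModelError(
            f"no rule for {target} satisfies the truth table together with "
            f"the logic labels; minimal conflicting row set: {conflict}"
        )
    return _pick(target, variables, candidates, edges, template)


def _satisfying(variables, signs, rows) -> list[dict]:
    try:
        cells = _fill_cells(variables, rows)
    except ModelError:
        return []
    return _search_functions(variables, signs, cells)


def _minimal_conflict(variables, signs, rows):
    """Greedy shrink of the row set to a still-unsatisfiable core."""
    core = list(rows)
    shrunk = True
    while shrunk:
        shrunk = False
        for i in range(len(core)):
            trial = core[:i] + core[i + 1:]
            if trial and not _satisfying(variables, signs, trial):
                core = trial
                shrunk = True
                break
    return core


def _pick(
    target: str,
    variables: Sequence[str],
    candidates: list[dict],
    edges: Sequence[LogicEdge],
    template: str,
) -> Resolution:
    exprs = [expression_from_truth_table(variables, t) for t in candidates]
    if len(exprs) == 1:
        return Resolution(BooleanFunction(target, exprs[0]), 1)
    # ambiguity: prefer the template-selected rule if it is a candidate
    notes = [f"{len(exprs)} candidate rules remained"]
    try:
        outcome = assemble_function(target, edges, template)
        tmpl = outcome.function
    except ModelError:
        tmpl = None
    if tmpl is not None:
        tmpl_table = {
            key: evaluate(tmpl.expression,
                          dict(zip(variables, key)) |
                          {v: 0 for v in tmpl.regulators if v not in variables})
            for key in candidates[0]
        }
        for t, e in zip(candidates, exprs):
            if t == tmpl_table:
                notes.append("template-selected rule chosen among candidates")
                return Resolution(
                    BooleanFunction(target, e), len(exprs), ambiguous=True,
                    notes=notes,
                )
    best = min(exprs, key=lambda e: (count_literals(e), str(canonicalize(e))))
    notes.append("fewest-literal rule chosen among candidates")
    return Resolution(
        BooleanFunction(target, best), len(exprs), ambiguous=True, notes=notes
    )
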