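"""Boolean expression trees in negation normal form.

Update rules are trees whose leaves are literals (a node name or its
negation) and whose internal operators are AND / OR.  Negation appears only
on leaves: this is exactly the grammar of the rules the inference method
emits (nested canalizing, unate functions), and it keeps every structural
manipulation — grouping regulators, joining a new dominant regulator,
dropping a literal — a purely local rewrite.

Node names are case-sensitive, whitespace-trimmed identifiers and may
contain characters such as ``/`` and ``+`` (``SPHK1/2``, ``Ca2+c``), which
real signalling-node names use freely.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Expr",
    "Lit",
    "And",
    "Or",
    "parse_expression",
    "truth_table",
    "essential_regulators",
    "semantic_equal",
    "expression_from_truth_table",
]

#: exhaustive truth tables are capped at this support size (desk-scale
#: guarantee; 2**16 rows).
MAX_SUPPORT = 16


class ExpressionError(ValueError):
    """Malformed expression or unsupported operation on one."""


@dataclass(frozen=True)
class Expr:
    """Base class for expression nodes."""

    def __str__(self) -> str:  # pragma: no cover - overridden
        raise NotImplementedError


@dataclass(frozen=True)
class Lit(Expr):
    name: str
    negated: bool = False

    def __str__(self) -> str:
        return f"not {self.name}" if self.negated else self.name


@dataclass(frozen=True)
class And(Expr):
    args: tuple[Expr, ...]

    def __str__(self) -> str:
        return " and ".join(_wrap(a) for a in self.args)


@dataclass(frozen=True)
class Or(Expr):
    args: tuple[Expr, ...]

    def __str__(self) -> str:
        return " or ".join(_wrap(a) for a in self.args)


def _wrap(e: Expr) -> str:
    return f"({e})" if isinstance(e, (And, Or)) else str(e)


def _sort_key(e: Expr) -> tuple:
    # literals first (by name, positive before negated), compound groups last
    if isinstance(e, Lit):
        return (0, e.name, e.negated)
    return (1, str(e))


def canonicalize(e: Expr) -> Expr:
    """Flatten nested same-operator groups and sort operands.

    The canonical order — literals sorted by node name, then nested groups —
    makes printed rules deterministic, e.g. ``T* = A or B or (C and D)``.
    """
    if isinstance(e, Lit):
        return e
    op = type(e)
    flat: list[Expr] = []
    for a in e.args:
        a = canonicalize(a)
        if isinstance(a, op):
            flat.extend(a.args)
        else:
            flat.append(a)
    # dedupe identical operands
    seen: dict[Expr, None] = {}
    for a in flat:
        seen.setdefault(a, None)
    args = tuple(sorted(seen, key=_sort_key))
    if len(args) == 1:
        return args[0]
    return op(args)


def support(e: Expr) -> tuple[str, ...]:
    """Variables appearing in ``e``, sorted by name."""
    names: set[str] = set()
    _collect(e, names)
    return tuple(sorted(names))


def _collect(e: Expr, out: set[str]) -> None:
    if isinstance(e, Lit):
        out.add(e.name)
    else:
        for a in e.args:
            _collect(a, out)


def evaluate(e: Expr, assignment: Mapping[str, int]) -> int:
    """Evaluate under a full 0/1 assignment of the support."""
    if isinstance(e, Lit):
        try:
            v = assignment[e.name]
        except KeyError:
            raise ExpressionError(f"unbound literal {e.name!r}") from None
        return (1 - v) if e.negated else int(v)
    if isinstance(e, And):
        return int(all(evaluate(a, assignment) for a in e.args))
    return int(any(evaluate(a, assignment) for a in e.args))


def evaluate_partial(e: Expr, assignment: Mapping[str, int | None]) -> int | None:
    """Kleene three-valued evaluation; ``None`` means undetermined.

    Sound but not complete (``A or not A`` with ``A`` unknown yields
    ``None``); the forced-state oracle falls back to enumeration over the
    unknown support for completeness.
    """
    if isinstance(e, Lit):
        v = assignment.get(e.name)
        if v is None:
            return None
        return (1 - v) if e.negated else int(v)
    vals = [evaluate_partial(a, assignment) for a in e.args]
    if isinstance(e, And):
        if any(v == 0 for v in vals):
            return 0
        if all(v == 1 for v in vals):
            return 1
        return None
    if any(v == 1 for v in vals):
        return 1
    if all(v == 0 for v in vals):
        return 0
    return None


def forced_value(e: Expr, assignment: Mapping[str, int | None]) -> int | None:
    """Value of ``e`` if identical under every completion of the unknowns.

    This operationalises "regardless of the state of other regulators":
    tautologies over unknown inputs are detected (unlike plain three-valued
    evaluation).
    """
    quick = evaluate_partial(e, assignment)
    if quick is not None:
        return quick
    free = [v for v in support(e) if assignment.get(v) is None]
    if len(free) > MAX_SUPPORT:
        raise ExpressionError(
            f"cannot decide forcing over {len(free)} unknown regulators "
            f"(limit {MAX_SUPPORT})"
        )
    fixed = {k: v for k, v in assignment.items() if v is not None}
    result: int | None = None
    for bits in itertools.product((0, 1), repeat=len(free)):
        fixed.update(zip(free, bits))
        v = evaluate(e, fixed)
        if result is None:
            result = v
        elif result != v:
            return None
    return result


def truth_table(e: Expr) -> list[tuple[dict[str, int], int]]:
    """Exhaustive truth table over the expression's support.

    Rows are ordered lexicographically by regulator name with assignments
    counted in binary (the first-named regulator is the most significant
    bit), so the table is deterministic.
    """
    vars_ = support(e)
    if len(vars_) > MAX_SUPPORT:
        raise ExpressionError(
            f"support of size {len(vars_)} exceeds the limit of {MAX_SUPPORT}"
        )
    rows = []
    for bits in itertools.product((0, 1), repeat=len(vars_)):
        asg = dict(zip(vars_, bits))
        rows.append((asg, evaluate(e, asg)))
    return rows


def essential_regulators(e: Expr) -> dict[str, str]:
    """Variables whose flip changes the output in at least one context.

    Returns ``{name: role}`` with role in ``{"activator", "inhibitor",
    "ambiguous"}``.  A variable absent from the result is redundant; rules
    in the biologically meaningful family contain no such variable and no
    ambiguous one.
    """
    vars_ = support(e)
    if len(vars_) > MAX_SUPPORT:
        raise ExpressionError(
            f"support of size {len(vars_)} exceeds the limit of {MAX_SUPPORT}"
        )
    out: dict[str, str] = {}
    for v in vars_:
        others = [w for w in vars_ if w != v]
        up = down = False
        for bits in itertools.product((0, 1), repeat=len(others)):
            asg = dict(zip(others, bits))
            asg[v] = 0
            f0 = evaluate(e, asg)
            asg[v] = 1
            f1 = evaluate(e, asg)
            if f1 > f0:
                up = True
            elif f1 < f0:
                down = True
        if up and down:
            out[v] = "ambiguous"
        elif up:
            out[v] = "activator"
        elif down:
            out[v] = "inhibitor"
    return out


def prune_redundant(e: Expr) -> Expr:
    """Re-express ``e`` over its essential variables only."""
    ess = sorted(essential_regulators(e))
    if tuple(ess) == support(e):
        return canonicalize(e)
    if not ess:
        # constant function: represent as a tautology/contradiction over the
        # first support variable if any, else fail loudly
        vars_ = support(e)
        if not vars_:
            raise ExpressionError("empty expression")
        v = vars_[0]
        const = evaluate(e, {w: 0 for w in vars_})
        return Or((Lit(v), Lit(v, True))) if const else And((Lit(v), Lit(v, True)))
    table = {}
    for bits in itertools.product((0, 1), repeat=len(ess)):
        asg = dict(zip(ess, bits))
        asg.update({w: 0 for w in support(e) if w not in asg})
        table[bits] = evaluate(e, asg)
    return expression_from_truth_table(ess, table)


def semantic_equal(f: Expr, g: Expr) -> bool:
    """True iff the two rules coincide after dropping redundant regulators.

    The criterion for counting an inferred rule as a correct re-discovery:
    equality of truth tables over the shared essential support.
    """
    fe = sorted(essential_regulators(f))
    ge = sorted(essential_regulators(g))
    if fe != ge:
        return False
    extra_f = {v: 0 for v in support(f) if v not in fe}
    extra_g = {v: 0 for v in support(g) if v not in ge}
    for bits in itertools.product((0, 1), repeat=len(fe)):
        asg = dict(zip(fe, bits))
        if evaluate(f, asg | extra_f) != evaluate(g, asg | extra_g):
            return False
    return True


def expression_from_truth_table(
    variables: Sequence[str], table: Mapping[tuple[int, ...], int]
) -> Expr:
    """Minimal-DNF expression for a fully specified truth table.

    Uses Quine-McCluskey minimisation (sympy's SOPform); the result is
    canonicalized.  Constant-1 / constant-0 tables come back as a tautology
    or contradiction over the first variable.
    """
    from sympy import symbols as _symbols
    from sympy.logic import SOPform
    from sympy.logic.boolalg import BooleanTrue, BooleanFalse

    variables = list(variables)
    if not variables:
        raise ExpressionError("truth table needs at least one variable")
    minterms = [list(bits) for bits, v in sorted(table.items()) if v]
    syms = _symbols([f"x{i}" for i in range(len(variables))])
    if not isinstance(syms, (list, tuple)):
        syms = [syms]
    sop = SOPform(list(syms), minterms)
    if isinstance(sop, BooleanTrue):
        v = variables[0]
        return Or((Lit(v), Lit(v, True)))
    if isinstance(sop, BooleanFalse):
        v = variables[0]
        return And((Lit(v), Lit(v, True)))
    name_of = {str(s): variables[i] for i, s in enumerate(syms)}
    return canonicalize(_from_sympy(sop, name_of))


def _from_sympy(node, name_of: Mapping[str, str]) -> Expr:
    from sympy import And as SAnd, Or as SOr, Not as SNot, Symbol

    if isinstance(node, Symbol):
        return Lit(name_of[str(node)])
    if isinstance(node, SNot):
        (arg,) = node.args
        return Lit(name_of[str(arg)], True)
    if isinstance(node, SAnd):
        return And(tuple(_from_sympy(a, name_of) for a in node.args))
    if isinstance(node, SOr):
        return Or(tuple(_from_sympy(a, name_of) for a in node.args))
    raise ExpressionError(f"unexpected sympy node {node!r}")


def count_literals(e: Expr) -> int:
    if isinstance(e, Lit):
        return 1
    return sum(count_literals(a) for a in e.args)


# ---------------------------------------------------------------------------
# parsing


class _Tokenizer:
    """Tokens for both the human dialect (and/or/not) and bnet (&, |, !).

    Identifiers are maximal runs of characters other than whitespace,
    parentheses, ``&``, ``|``, ``!`` and ``,`` — permissive on purpose so
    names like ``SPHK1/2``, ``Ca2+c`` and ``8-nitro-cGMP`` pass through.
    """

    SPECIAL = set("()&|!,")

    def __init__(self, text: str):
        self.tokens = self._tokenize(text)
        self.pos = 0

    def _tokenize(self, text: str) -> list[str]:
        out: list[str] = []
        i, n = 0, len(text)
        while i < n:
            c = text[i]
            if c.isspace():
                i += 1
                continue
            if c in self.SPECIAL:
                out.append(c)
                i += 1
                continue
            j = i
            while j < n and not text[j].isspace() and text[j] not in self.SPECIAL:
                j += 1
            out.append(text[i:j])
            i = j
        return out

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ExpressionError("unexpected end of expression")
        self.pos += 1
        return tok


_OR_WORDS = {"or", "OR", "|"}
_AND_WORDS = {"and", "AND", "&"}
_NOT_WORDS = {"not", "NOT", "!"}


def parse_expression(text: str) -> Expr:
    """Parse ``A or B or (C and D)`` / bnet ``A | B | (C & D)`` syntax."""
    tz = _Tokenizer(text)
    e = _parse_or(tz)
    if tz.peek() is not None:
        raise ExpressionError(f"trailing tokens near {tz.peek()!r} in {text!r}")
    return canonicalize(e)


def _parse_or(tz: _Tokenizer) -> Expr:
    args = [_parse_and(tz)]
    while tz.peek() in _OR_WORDS:
        tz.next()
        args.append(_parse_and(tz))
    return args[0] if len(args) == 1 else Or(tuple(args))


def _parse_and(tz: _Tokenizer) -> Expr:
    args = [_parse_atom(tz)]
    while tz.peek() in _AND_WORDS:
        tz.next()
        args.append(_parse_atom(tz))
    return args[0] if len(args) == 1 else And(tuple(args))


def _parse_atom(tz: _Tokenizer) -> Expr:
    tok = tz.next()
    if tok in _NOT_WORDS:
        inner = _parse_atom(tz)
        if not isinstance(inner, Lit):
            raise ExpressionError("negation is only supported on literals")
        return Lit(inner.name, not inner.negated)
    if tok == "(":
        e = _parse_or(tz)
        if tz.next() != ")":
            raise ExpressionError("missing closing parenthesis")
        return e
    if tok in {")", "&", "|", "!", ","}:
        raise ExpressionError(f"unexpected token {tok!r}")
    return Lit(tok)
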