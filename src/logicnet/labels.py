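"""Causal-logic labels and their composition algebra.

Each non-unknown label is one or two canalizing implications
``R = trigger  =>  T = forced`` that hold regardless of the state of any
other regulator of T:

=============================  ========  =======
label                          trigger   forced
=============================  ========  =======
sufficient                     1         1
sufficient_inhibitory          1         0
necessary                      0         0
necessary_inhibitory           0         1
=============================  ========  =======

The two "sufficient and necessary" labels carry both implications of the
corresponding sign and force the target to mirror (or invert) the
regulator exactly.

Two labels incident on the same target are compatible exactly when they
force the target to the *same* value (a forced-to-1 pair of implications
can coexist in an OR-rule, a forced-to-0 pair in an AND-rule); labels
forcing opposite values contradict each other for some regulator state.
"""

from __future__ import annotations

from enum import Enum

__all__ = ["LogicLabel", "compose_implications", "compose_pair_sets"]


class LogicLabel(str, Enum):
    SUFFICIENT = "sufficient"
    NECESSARY = "necessary"
    SUFFICIENT_INHIBITORY = "sufficient_inhibitory"
    NECESSARY_INHIBITORY = "necessary_inhibitory"
    SUFFICIENT_AND_NECESSARY = "sufficient_and_necessary"
    SUFFICIENT_AND_NECESSARY_INHIBITORY = "sufficient_and_necessary_inhibitory"
    UNKNOWN = "unknown"

    # -- structure ---------------------------------------------------------

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        """The (trigger, forced) implication pairs this label asserts."""
        return _PAIRS[self]

    @property
    def sign(self) -> str:
        """'+' for promoting labels, '-' for inhibitory, '?' for unknown."""
        if self is LogicLabel.UNKNOWN:
            return "?"
        return "-" if "inhibitory" in self.value else "+"

    @property
    def is_basic(self) -> bool:
        """One of the four single-implication labels."""
        return len(_PAIRS[self]) == 1

    @property
    def is_sufficient_type(self) -> bool:
        """Triggered by the regulator's ON state (trigger = 1)."""
        return any(t == 1 for t, _ in _PAIRS[self])

    def constituents(self) -> tuple["LogicLabel", ...]:
        """Basic labels making up this label (s&n decomposes into two)."""
        return tuple(_FROM_PAIR[p] for p in _PAIRS[self])


_PAIRS: dict[LogicLabel, tuple[tuple[int, int], ...]] = {
    LogicLabel.SUFFICIENT: ((1, 1),),
    LogicLabel.SUFFICIENT_INHIBITORY: ((1, 0),),
    LogicLabel.NECESSARY: ((0, 0),),
    LogicLabel.NECESSARY_INHIBITORY: ((0, 1),),
    LogicLabel.SUFFICIENT_AND_NECESSARY: ((1, 1), (0, 0)),
    LogicLabel.SUFFICIENT_AND_NECESSARY_INHIBITORY: ((1, 0), (0, 1)),
    LogicLabel.UNKNOWN: (),
}

_FROM_PAIR = {
    (1, 1): LogicLabel.SUFFICIENT,
    (1, 0): LogicLabel.SUFFICIENT_INHIBITORY,
    (0, 0): LogicLabel.NECESSARY,
    (0, 1): LogicLabel.NECESSARY_INHIBITORY,
}


def label_from_pairs(pairs: frozenset | set | tuple) -> LogicLabel | None:
    """Label asserting exactly the given implication pairs, if one exists."""
    ps = frozenset(pairs)
    if not ps:
        return None
    if len(ps) == 1:
        return _FROM_PAIR[next(iter(ps))]
    if ps == frozenset({(1, 1), (0, 0)}):
        return LogicLabel.SUFFICIENT_AND_NECESSARY
    if ps == frozenset({(1, 0), (0, 1)}):
        return LogicLabel.SUFFICIENT_AND_NECESSARY_INHIBITORY
    return None  # mixed-sign pair sets have no single-label name


def compose_implications(first: LogicLabel, second: LogicLabel) -> LogicLabel | None:
    """Compose two basic implications along a two-step path.

    ``first`` relates R to a mediator M, ``second`` relates M to T.  The
    chain carries an implication exactly when the state ``first`` forces on
    M is the state that triggers ``second``; the composite then inherits
    ``first``'s trigger and ``second``'s forced state.  Returns ``None``
    when no implication survives (e.g. sufficient followed by necessary:
    R = ON forces M = ON, but the necessary implication only fires on
    M = OFF).
    """
    for lab in (first, second):
        if lab is LogicLabel.UNKNOWN:
            raise ValueError("cannot compose an unknown logic label")
        if not lab.is_basic:
            raise ValueError(
                f"{lab.value} must be decomposed into its constituent "
                "implications before composition"
            )
    (t1, f1), = first.pairs
    (t2, f2), = second.pairs
    if f1 != t2:
        return None
    return _FROM_PAIR[(t1, f2)]


def compose_pair_sets(
    first: frozenset[tuple[int, int]], second: frozenset[tuple[int, int]]
) -> frozenset[tuple[int, int]]:
    """Setwise composition, used when a chain contains s&n labels."""
    out = set()
    for t1, f1 in first:
        for t2, f2 in second:
            if f1 == t2:
                out.add((t1, f2))
    return frozenset(out)
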