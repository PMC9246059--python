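"""Co-pointing inference: resolving conflicts by inferring new edges.

When an (indirectly) sufficient-type regulator S and a necessary-type
regulator N force the same target to opposite values, the conflict
dissolves if N is in fact a mediator of the pathway from S: the
co-pointing subgraph theorem then implies that S's ON state forces N's
state.  Concretely, with S triggering on ON and forcing T to v, and N's
implication triggering on state t and forcing T to the opposite value,
S = ON must force N to the non-triggering state 1 - t:

* S sufficient for T, N necessary for T           →  S sufficient for N
* S sufficient for T, N sufficient-inhibitory T   →  S sufficient-inhibitory N
* S sufficient-inhibitory T, N necessary-inhib. T →  S sufficient for N

Two sufficient regulators force the same value, so no inference is made.
The theorem needs N to be a non-source node and applies in the extended
form where S need not be a source, provided no path runs from N to S.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .labels import LogicLabel
from .model import Confidence, Directness, LogicEdge, RegulatoryNetwork

__all__ = ["CopointingInference", "apply_copointing"]


@dataclass(frozen=True)
class CopointingInference:
    sufficient_node: str
    necessary_node: str
    shared_target: str
    inferred: LogicEdge


def _basic(edge: LogicEdge) -> tuple[int, int] | None:
    if edge.logic.is_basic:
        return edge.logic.pairs[0]
    return None


def apply_copointing(
    edges: Sequence[LogicEdge], network: RegulatoryNetwork
) -> list[CopointingInference]:
    """One pass of co-pointing inference over all targets.

    For every target with a conflicting pair of basic labels where the
    sufficient-type side S is indirect, the other regulator N is a
    non-source node and no path N→S exists, infer the S→N edge dictated
    by the trigger states.  Inferred edges are tagged mediator-sharing so
    they re-enter the integration step.  Non-applicable configurations
    are skipped.
    """
    non_source = {e.target for e in edges} | {
        e.target for e in network.edges
    }
    by_target: dict[str, list[LogicEdge]] = {}
    for e in edges:
        if _basic(e) is not None:
            by_target.setdefault(e.target, []).append(e)

    inferences: list[CopointingInference] = []
    seen_pairs: set[tuple[str, str, str]] = set()
    for target in sorted(by_target):
        incident = sorted(by_target[target], key=lambda e: e.key)
        for i, e1 in enumerate(incident):
            for e2 in incident[i + 1:]:
                if e1.regulator == e2.regulator:
                    continue
                (t1, f1) = _basic(e1)
                (t2, f2) = _basic(e2)
                if f1 == f2:
                    continue  # same forced value: compatible, nothing to infer
                # choose the S role: trigger ON, indirect; prefer the
                # promoting sufficient edge when both orderings qualify
                orderings = []
                for s_edge, n_edge in ((e1, e2), (e2, e1)):
                    ts, _ = _basic(s_edge)
                    if ts != 1:
                        continue
                    if s_edge.directness is Directness.DIRECT:
                        continue
                    if n_edge.regulator not in non_source:
                        continue
                    if network.has_path(n_edge.regulator, s_edge.regulator):
                        continue
                    orderings.append((s_edge, n_edge))
                if not orderings:
                    continue
                orderings.sort(
                    key=lambda pair: (pair[0].sign != "+", pair[0].key)
                )
                s_edge, n_edge = orderings[0]
                tn, _ = _basic(n_edge)
                logic = (
                    LogicLabel.SUFFICIENT if tn == 0
                    else LogicLabel.SUFFICIENT_INHIBITORY
                )
                key = (s_edge.regulator, n_edge.regulator, logic.sign)
                if key in seen_pairs:
                    continue
                seen_pairs.add(key)
                confidence = (
                    Confidence.LOW
                    if Confidence.LOW in (s_edge.confidence, n_edge.confidence)
                    else Confidence.HIGH
                )
                inferred = LogicEdge(
                    regulator=s_edge.regulator,
                    target=n_edge.regulator,
                    sign=logic.sign,
                    logic=logic,
                    directness=Directness.INDIRECT_SHARED,
                    confidence=confidence,
                    provenance=(
                        f"co-pointing at {target} "
                        f"({s_edge.logic.value} vs {n_edge.logic.value})"
                    ),
                )
                inferences.append(
                    CopointingInference(
                        sufficient_node=s_edge.regulator,
                        necessary_node=n_edge.regulator,
                        shared_target=target,
                        inferred=inferred,
                    )
                )
    return inferences
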