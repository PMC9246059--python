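"""Co-pointing inference: turning a conflict into a new relationship.

The hormone signal ABA is (indirectly) sufficient for stomatal closure;
a knockout shows the guanylate cyclase NOGC1 is necessary for closure.
Sufficient and necessary regulators of the same target contradict each
other — unless NOGC1 is a mediator of the pathway from ABA.  Since NOGC1
is not a source node and no path runs from NOGC1 back to ABA, the
co-pointing subgraph theorem concludes that ABA must be sufficient for
NOGC1.
"""

from logicnet import Directness, LogicEdge, LogicLabel, RegulatoryNetwork, apply_copointing

S, N = LogicLabel.SUFFICIENT, LogicLabel.NECESSARY
SHARED = Directness.INDIRECT_SHARED

edges = [
    LogicEdge("ABA", "Closure", "+", S, directness=SHARED),
    LogicEdge("NOGC1", "Closure", "+", N, directness=SHARED),
    LogicEdge("NO", "NOGC1", "+", S),  # NOGC1 is NO-dependent: not a source
]

for inf in apply_copointing(edges, RegulatoryNetwork(edges=edges)):
    print(f"at target {inf.shared_target}: "
          f"{inf.sufficient_node} must be {inf.inferred.logic.value} "
          f"for {inf.necessary_node}")

# Two sufficient regulators, by contrast, force the target to the same
# value and license no inference at all:
agreeing = [
    LogicEdge("B", "C", "+", S, directness=SHARED),
    LogicEdge("A", "C", "+", S, directness=SHARED),
    LogicEdge("Z", "A", "+", S),
]
print("inferences from two sufficient regulators:",
      apply_copointing(agreeing, RegulatoryNetwork(edges=agreeing)))
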