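"""Integrating indirect relationships and pruning redundant edges.

Two complementary situations from signalling-network curation:

1. OST1 is reported sufficient for calcium influx (CaIM), but the only
   existing route OST1 → RBOH → ROS → GHR1 → CaIM carries no net logic
   implication — so an independent sufficient edge is added and OR-joined
   into CaIM's rule.
2. A redundant indirect sufficient edge TCF/LEF → SNAI1 duplicates the
   sufficient path through GLI, so logic binary transitive reduction
   removes it while the implication keeps holding through the path.
"""

from logicnet import (
    BooleanFunction,
    BooleanModel,
    Directness,
    LogicEdge,
    LogicLabel,
    RegulatoryNetwork,
    check_implication,
    integrate_indirect,
    lbtr_reduce,
)

S, N, NI, U = (LogicLabel.SUFFICIENT, LogicLabel.NECESSARY,
               LogicLabel.NECESSARY_INHIBITORY, LogicLabel.UNKNOWN)

# -- case 1: path with the wrong logic --------------------------------------
edges = [
    LogicEdge("OST1", "RBOH", "+", N),
    LogicEdge("RBOH", "ROS", "+", N),
    LogicEdge("ROS", "GHR1", "+", N),
    LogicEdge("GHR1", "CaIM", "+", U),
    LogicEdge("ActinReorganization", "CaIM", "+", S),
    LogicEdge("NtSyp121", "CaIM", "+", U),
    LogicEdge("MRP5", "CaIM", "+", U),
    LogicEdge("ABH1", "CaIM", "-", NI),
    LogicEdge("ERA1", "CaIM", "-", NI),
]
net = RegulatoryNetwork(edges=edges)
fns = [
    BooleanFunction.parse("RBOH", "OST1"),
    BooleanFunction.parse("ROS", "RBOH"),
    BooleanFunction.parse("GHR1", "ROS"),
    BooleanFunction.parse(
        "CaIM",
        "ActinReorganization or (NtSyp121 and GHR1 and MRP5) "
        "or not ABH1 or not ERA1",
    ),
]
model = BooleanModel(fns, sources=sorted(net.nodes - {f.target for f in fns}))
pending = [LogicEdge("OST1", "CaIM", "+", S,
                     directness=Directness.INDIRECT_SHARED)]
model, actions = integrate_indirect(model, net, pending)
print("decision:", actions[0].decision)
print("new rule:", model.functions["CaIM"])
print("OST1 now sufficient for CaIM:",
      check_implication(model, "OST1", S, "CaIM"))

# -- case 2: redundant indirect edge ----------------------------------------
edges2 = [
    LogicEdge("TCF/LEF", "GLI", "+", S),
    LogicEdge("GLI", "SNAI1", "+", S),
    LogicEdge("TCF/LEF", "SNAI1", "+", S,
              directness=Directness.INDIRECT_INDEPENDENT),
]
net2 = RegulatoryNetwork(edges=edges2)
model2 = BooleanModel(
    [BooleanFunction.parse("GLI", "TCF/LEF"),
     BooleanFunction.parse("SNAI1", "GLI or TCF/LEF")],
    sources=["TCF/LEF"],
)
net2, removed = lbtr_reduce(model2, net2)
print("\nedges removed by reduction:", [str(e) for e in removed])
print("reduced rule:", model2.functions["SNAI1"])
print("implication preserved through the path:",
      check_implication(model2, "TCF/LEF", S, "SNAI1"))
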