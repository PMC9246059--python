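"""Shared fixtures: small hand-built networks from the worked case studies."""

import pytest

from logicnet import (
    BooleanFunction,
    BooleanModel,
    Directness,
    LogicEdge,
    LogicLabel,
    RegulatoryNetwork,
)

S = LogicLabel.SUFFICIENT
N = LogicLabel.NECESSARY
SI = LogicLabel.SUFFICIENT_INHIBITORY
NI = LogicLabel.NECESSARY_INHIBITORY
SN = LogicLabel.SUFFICIENT_AND_NECESSARY
U = LogicLabel.UNKNOWN
SHARED = Directness.INDIRECT_SHARED
INDEP = Directness.INDIRECT_INDEPENDENT


def model_from(net: RegulatoryNetwork, *rules: str) -> BooleanModel:
    fns = [BooleanFunction.parse(*r.split("=", 1)) for r in rules]
    fns = [BooleanFunction(f.target.strip(), f.expression) for f in fns]
    return BooleanModel(fns, sources=sorted(net.nodes - {f.target for f in fns}))


@pytest.fixture
def two_suff_two_nec_edges():
    """Two sufficient and two necessary regulators of one target."""
    return [
        LogicEdge("A", "T", "+", S),
        LogicEdge("B", "T", "+", S),
        LogicEdge("C", "T", "+", N),
        LogicEdge("D", "T", "+", N),
    ]


@pytest.fixture
def aba_closure():
    """ABA sufficient for closure, NOGC1 necessary, NOGC1 non-source."""
    edges = [
        LogicEdge("ABA", "Closure", "+", S, directness=SHARED),
        LogicEdge("NOGC1", "Closure", "+", N, directness=SHARED),
        LogicEdge("NO", "NOGC1", "+", S),
    ]
    return edges, RegulatoryNetwork(edges=edges)


@pytest.fixture
def caim_network():
    """The stomatal CaIM neighbourhood: OST1 reaches CaIM only through a
    path with no net logic implication."""
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
    model = model_from(
        net,
        "RBOH = OST1",
        "ROS = RBOH",
        "GHR1 = ROS",
        "CaIM = ActinReorganization or (NtSyp121 and GHR1 and MRP5) "
        "or not ABH1 or not ERA1",
    )
    return model, net


@pytest.fixture
def closure_chain():
    """SLAC1 → AnionEM → H2O efflux → Closure, all necessary."""
    edges = [
        LogicEdge("SLAC1", "AnionEM", "+", N),
        LogicEdge("X", "AnionEM", "+", N),
        LogicEdge("AnionEM", "H2O_Efflux", "+", N),
        LogicEdge("Y", "H2O_Efflux", "+", N),
        LogicEdge("H2O_Efflux", "Closure", "+", N),
        LogicEdge("Z", "Closure", "+", N),
    ]
    net = RegulatoryNetwork(edges=edges)
    model = model_from(
        net,
        "AnionEM = SLAC1 and X",
        "H2O_Efflux = AnionEM and Y",
        "Closure = H2O_Efflux and Z",
    )
    return model, net


@pytest.fixture
def cgmp_chain():
    """NOGC1 → cGMP → 8-nitro-cGMP, both necessary."""
    edges = [
        LogicEdge("NOGC1", "cGMP", "+", N),
        LogicEdge("W", "cGMP", "+", N),
        LogicEdge("cGMP", "8-nitro-cGMP", "+", N),
        LogicEdge("V", "8-nitro-cGMP", "+", N),
    ]
    net = RegulatoryNetwork(edges=edges)
    model = model_from(
        net,
        "cGMP = NOGC1 and W",
        "8-nitro-cGMP = cGMP and V",
    )
    return model, net


@pytest.fixture
def snai1_network():
    """TCF/LEF → GLI → SNAI1 sufficient path plus a redundant indirect
    sufficient edge TCF/LEF → SNAI1."""
    edges = [
        LogicEdge("TCF/LEF", "GLI", "+", S),
        LogicEdge("GLI", "SNAI1", "+", S),
        LogicEdge("TCF/LEF", "SNAI1", "+", S, directness=INDEP),
    ]
    net = RegulatoryNetwork(edges=edges)
    model = model_from(net, "GLI = TCF/LEF", "SNAI1 = GLI or TCF/LEF")
    return model, net
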