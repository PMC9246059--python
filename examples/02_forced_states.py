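"""The forced-state oracle: what does clamping a node imply?

A causal-logic implication claims that a sustained regulator state fixes
the target's state regardless of every other regulator.  On a full
Boolean model this is decided by the logical domain of influence (LDOI):
clamp the regulator, propagate three-valued states to a fixpoint, and
read off which nodes end up forced.
"""

from logicnet import BooleanFunction, BooleanModel, LogicLabel, check_implication, ldoi

model = BooleanModel(
    [
        BooleanFunction.parse("M", "R"),
        BooleanFunction.parse("T", "M and X"),
        BooleanFunction.parse("Y", "T or not T"),
    ],
    sources=["R", "X"],
)

state = ldoi(model, {"R": 0})
print("clamp R=0 forces:", state.forced_nodes())
# M and T collapse to 0 through the AND chain; Y is a tautology and is
# forced to 1 under every completion — plain three-valued logic would
# miss it, the oracle does not.

print("R necessary for T:",
      check_implication(model, "R", LogicLabel.NECESSARY, "T"))
print("X sufficient for T:",
      check_implication(model, "X", LogicLabel.SUFFICIENT, "T"))
# X=1 alone leaves T undetermined (M free), so X is not sufficient.
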