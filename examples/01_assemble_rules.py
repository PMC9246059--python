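"""Assembling a Boolean update rule from causal-logic labels.

Four regulators of one target carry conflicting labels: A and B are
sufficient (their ON state alone turns T on) while C and D are necessary
(their OFF state alone turns T off).  Sufficient and necessary labels
cannot coexist in one rule, so the dominant-regulators method offers two
resolutions: group the necessary side into a collectively-sufficient AND
block, or group the sufficient side into a collectively-necessary OR
block.
"""

from logicnet import LogicEdge, LogicLabel, assemble_function, check_compatibility

S, N = LogicLabel.SUFFICIENT, LogicLabel.NECESSARY

edges = [
    LogicEdge("A", "T", "+", S),
    LogicEdge("B", "T", "+", S),
    LogicEdge("C", "T", "+", N),
    LogicEdge("D", "T", "+", N),
]

ok, conflicts = check_compatibility([e.logic for e in edges])
print(f"labels compatible: {ok}; conflicting pairs: "
      f"{[(a.value, b.value) for a, b in conflicts]}")

for template in ("sufficient_dominant", "necessary_dominant"):
    outcome = assemble_function("T", edges, template)
    print(f"{template:>20}: {outcome.function}   [{outcome.status}]")

# With the sufficient-dominant template the rule reads: T activates when
# any sufficient regulator is on, or when *all* grouped necessary
# regulators are on together; the necessary-dominant template instead
# demands every necessary regulator plus at least one of the grouped
# sufficient ones.
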