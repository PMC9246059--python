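# logicnet

Boolean network inference from causal logic implications.

Building a Boolean model of a signalling or regulatory process by hand means
reading hundreds of perturbation experiments and turning each into an edge
and, eventually, an update rule per node.  `logicnet` automates the logical
core of that process for systems biologists: it takes a table of causal
statements — "knockout of R abolishes T", "sustained supply of X activates
Y", "A promotes (B induces C)" — and produces a parsimonious signed network
together with one Boolean update rule per node that preserves the stated
implications.

## The causal-logic calculus

Each statement is distilled into a *causal logic implication*, a canalizing
relationship between a regulator R and a target T that holds regardless of
T's other regulators:

| implication            | meaning            | rule form          |
|------------------------|--------------------|--------------------|
| sufficient             | R = ON ⇒ T = ON    | `T* = R or …`      |
| sufficient inhibitory  | R = ON ⇒ T = OFF   | `T* = not R and …` |
| necessary              | R = OFF ⇒ T = OFF  | `T* = R and …`     |
| necessary inhibitory   | R = OFF ⇒ T = ON   | `T* = not R or …`  |

(`T*` denotes the next-timestep state; a regulator that is both sufficient
and necessary must be the sole regulator, `T* = R`.)

Two labels on the same target are compatible exactly when they force the
target to the same value; an OR-rule preserves the forced-to-ON labels, an
AND-rule the forced-to-OFF ones.  On top of this calculus the package
implements:

* **composition along paths** — an indirect relationship is carried by a
  path whose stepwise implications chain (the forced state of one step must
  trigger the next);
* **the forced-state oracle (LDOI)** — clamp a node in a model, propagate
  three-valued states to the unique least fixpoint, and decide any claimed
  implication semantically, including subgraph- and feedback-mediated ones;
* **co-pointing inference** — when an indirectly sufficient regulator S and
  a necessary regulator N contradict each other at a shared target, and N is
  a non-source node with no path back to S, S must be sufficient for N: a
  new testable relationship;
* **dominant-regulators resolution** — irreducible conflicts are resolved by
  one of two templates (group the necessary side into a collectively
  sufficient AND block, or the sufficient side into a collectively necessary
  OR block), or manually from experiment context / partial truth tables;
* **integration of mediator-sharing indirect relationships** — each is first
  checked against the model; an edge is added only when no path or subgraph
  realises it, optionally completing a path through a declared mediator;
* **logic binary transitive reduction (l-BTR)** — non-direct edges that
  duplicate a path of the same sign and composed logic are removed, with a
  conservation re-check after every removal.

A synthetic benchmark (`logicnet.bench`) generates ground-truth models in
the rule family the grammar can express, derives per-edge observations,
corrupts them the way real inputs are incomplete, and scores how many rules
are re-inferred up to semantic equality.

## Worked example

Four regulators of one target with conflicting labels — A and B sufficient,
C and D necessary (run `python examples/01_assemble_rules.py`):

```
labels compatible: False; conflicting pairs: [('sufficient', 'necessary'), ...]
 sufficient_dominant: T* = A or B or (C and D)   [resolved_template1]
  necessary_dominant: T* = C and D and (A or B)   [resolved_template2]
```

The first template treats sufficient regulators as dominant and marks the
necessary regulators as collectively sufficient; the second demands every
necessary regulator plus at least one of the grouped sufficient ones.  Both
candidates are recorded in the inference report; the choice is a flag.

The same library drives a shell workflow:

```sh
logicnet synth --n-nodes 20 --seed 42 --out-dir demo      # ground truth + statements
logicnet infer demo/statements.tsv --out-bnet demo/inferred.bnet \
    --out-sif demo/network.sif --report demo/report.json
logicnet score demo/truth.bnet demo/inferred.bnet
```

`infer` prints a one-line summary (rules, edges, incompatible targets,
co-pointing inferences, reduced edges) and exits non-zero if any retained
implication fails the final forced-state check.  `examples/` holds further
narrative scripts: forced-state propagation, co-pointing, indirect-edge
integration and reduction, and the recovery benchmark.

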