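# Methods

This note documents the model behind `logicnet`, the choices made where the
design was genuinely open, and what the synthetic benchmark does and does
not show.

## The causal-logic model

A Boolean model assigns every non-source node one update rule over literals
(a regulator or its negation) combined with AND/OR.  A *causal logic
implication* is a canalizing claim: one state of the regulator fixes the
target's state irrespective of all other regulators.  The four basic labels
are encoded internally as (trigger, forced) pairs — sufficient (1→1),
sufficient inhibitory (1→0), necessary (0→0), necessary inhibitory (0→1) —
and the two sufficient-and-necessary labels carry both pairs of their sign.

Two consequences of this encoding organise the whole package:

* **Compatibility.**  Labels incident on one target are jointly satisfiable
  by a single rule exactly when they force the target to the same value:
  forced-to-1 labels live in an OR-rule, forced-to-0 labels in an AND-rule.
  This reproduces the published 4×4 compatibility matrix cell for cell and
  explains why a sufficient-and-necessary regulator must be alone (it forces
  both values).
* **Composition.**  Implications chain along a path iff the forced state of
  each step is the trigger of the next; the composite keeps the first
  trigger and the last forced state.  Sufficient-and-necessary labels
  compose setwise over their constituent pairs.

### The forced-state oracle

`ldoi(model, clamp)` computes the logical domain of influence: the unique
least fixpoint of three-valued propagation in which a node becomes forced
to v when its rule evaluates to v under *every* completion of its
currently-unknown regulators.  Plain Kleene evaluation is used as a fast
path and an exhaustive check over the unknown support (≤16 regulators per
node, enforced) handles tautological forcing, so the oracle is complete for
this rule grammar, including subgraph- and feedback-mediated implications.
Clamped nodes keep their clamped value regardless of their own rules.
Values are only ever added, never retracted, hence the result is
order-independent; the test suite verifies this by renaming nodes (which
permutes the internal propagation order).

`check_implication` reduces every label to LDOI queries (one per
constituent pair).  A supporting path of matching composed label implies
the LDOI check (soundness, property-tested); the converse is false, which
is why integration consults the semantic oracle before searching for paths.

## Pipeline design choices

**Distillation.**  The evidence→logic mapping (knockout ⇒ necessary-type,
constitutive activation / supply ⇒ sufficient-type, reaction / physical
interaction ⇒ directness only) is table-driven and overridable, since these
are only the most common experimental designs.  Three-node statements
"A promotes/inhibits (B induces/inhibits C)" always decompose into an inner
sufficient-type edge B→C and a modulator edge A→C whose sign is the product
of the two stated signs; the modulator edge is tagged mediator-sharing so
it enters path/subgraph integration rather than direct rule assembly.

**Co-pointing.**  Implemented via the forced-value framing: a conflict is a
pair of labels forcing opposite values.  The sufficient-type (trigger-ON)
side plays the signal role S and must be indirect; the other regulator N
must be a non-source with no path N→S (the theorem's extended form).  The
inferred label is sufficient when N's trigger is OFF and sufficient
inhibitory when it is ON, which covers all three published sub-cases with
one rule.  When both sides trigger on ON, the promoting edge is preferred
as the signal.  After an inference, the signal's conflicting edge is
reclassified as mediator-sharing — its implication is now expected to run
through N — and passes through integration, where it typically resolves to
"already realised by a path".  The inference loop iterates to a fixpoint
with a pass cap of |nodes|.

**Assembly.**  Duplicate statements about the same regulator merge to the
strictest label (sufficient + necessary ⇒ sufficient-and-necessary);
opposite-sign duplicates are demoted to sign-only and flagged for manual
attention.  Sign-only regulators join the resolved side of the rule with
that side's operator, keeping their sign as the literal polarity — this
preserves every labelled implication, which OR-joining a sign-only
regulator into an AND-rule would not.  In the templates they follow their
sign group (promoting ⇒ sufficient side, inhibitory ⇒ grouped/negated).
Low-confidence labels lose ties: when demoting only the low-confidence side
of a conflict restores compatibility, that is done (and reported) before a
template is invoked.  The default template is sufficient-dominant; both
candidates are always recorded when requested.

**Manual resolution.**  Context-based resolution turns each label into a
truth-table row: trigger state of its regulator plus the assumed states of
co-regulators during that experiment; labels without context assert their
row universally but are overridden by contexted rows where they overlap
(that is precisely how the "R2 was ON during the R1 knockout" assumption
turns an OR into an AND).  Partial-truth-table resolution treats the given
rows and all label rows as hard constraints.  Candidates are enumerated
exhaustively over ≤4 regulators (65,536 tables), filtered to rules that are
unate in each regulator's stated sign with no redundant regulator, and
selected by fewest literals (after Quine–McCluskey minimisation via sympy)
then lexicographic canonical form; ambiguity is reported, and an
unsatisfiable instance reports a greedily minimised conflicting row core.

**Integration order.**  Pending mediator-sharing edges are processed in
lexicographic (target, regulator) order — the published procedure is
case-by-case with no stated order, and determinism matters more than any
particular order because the conservation re-check makes the outcome
order-robust.  The decision ladder per pending S→T with label L: (1) the
implication already holds on the model (LDOI) — record the supporting
path(s) as mediator hypotheses, add nothing; (2) paths exist but none
carries L — add an independent edge; (3) no path, and a pathway-support
anchor M is declared in the input — complete the path by adding S→M when M
regulates T (or M→T when S→M exists), with the unique label that composes
to L; (4) otherwise add an independent edge.  Pathway support is always an
explicit input flag, never guessed.  Added regulators join the target's
rule at the top with their family operator, i.e. they become canalizing
(dominant); when the new label conflicts with existing ones, the
overridden labels are recorded so the conservation check does not claim
them.

**Reduction.**  l-BTR candidates are non-direct labelled edges, tried
longest-spanning first (ties lexicographic).  An edge is removed when a
simple path of the same sign and composed logic survives without it, the
literal is dropped from the target's rule, and every implication that held
before the removal is re-verified by the oracle — any violation rolls the
removal back.  This re-check is deliberately stricter than the path
condition alone: it guarantees conservation even where path logic and
model-level forcing diverge.  The sweep repeats to a fixpoint and is
idempotent.

**Conservation.**  "Preserving each initially encoded causal relation"
cannot hold verbatim for labels the method itself weakens: template
grouping, low-confidence demotion, and dominant edge additions all replace
an individual claim by a collective one.  The final check therefore covers
every *retained* implication — all labelled input and inferred edges except
those the report lists as grouped, demoted, or overridden — and the
pipeline exits non-zero when any of them fails.  Under the synthetic study
conditions below no label is ever weakened, so the check covers the entire
input.

## The synthetic benchmark

`generate_model` draws a weakly connected acyclic network: nodes are
ordered, the first ~15% (at least one) are sources, and each later node
takes 1–3 regulators (default `max_in_degree=3`) from strictly earlier
nodes.  Default size is 20 nodes — large enough for multi-regulator
targets, chains for indirection corruption, and sub-second pipeline runs.
Literals are negated with probability 0.25, giving all four basic labels
healthy representation.  The default `single_layer` family (pure OR, pure
AND, or a single literal) is exactly the set of rules uniquely determined
by their per-edge labels, so perfect recovery from full input is the
correct oracle.  The `two_layer` family adds one nested group whose members
are observable only as signs; it probes the method's documented limit and
recovery below 1 is expected there.

`derive_statements` reads one direct pair statement per edge off the rules
(OR-literal ⇒ sufficient, AND-literal ⇒ necessary, negated forms ⇒
inhibitory, sole regulator ⇒ sufficient-and-necessary, nested-group member
⇒ sign only).  `corrupt_statements` then (a) adds redundant indirect
statements over composable two-node paths between otherwise unrelated
node pairs, (b) replaces such paths by an indirect statement of the
composed label, deleting one constituent at random and recording the
mediator as the declared support anchor — the information a curator would
in fact have — and (c) drops a fixed fraction of statements uniformly.
Statement drop is uniform and unstratified because nothing more specific
is known about how real inputs are incomplete; node-wise information loss
can be emulated by dropping all statements of a target externally.

Scoring is per-node semantic equality (identical truth tables over the
essential support); truth sources are excluded from the denominator unless
the inference wrongly assigned them a rule, and lost nodes count as
incorrect.

What passing shows — and does not.  Perfect round-trip recovery shows the
pipeline inverts its own observation model on the representable family; it
does not show that real literature statements are this clean.  The
generator produces acyclic networks only (feedback enters the package's
tests through hand-built cyclic cases, not the benchmark), observation
noise is absence, never a *wrong* label, and corruption never introduces
the contradictory duplicate statements real curation produces.  Recovery
under statement drop degrades because targets lose regulators entirely;
this measures sensitivity to missing information, not robustness to error.

## Numerical and degenerate-input conventions

* Expressions are negation-normal trees; canonical form flattens nested
  same-operator groups, deduplicates operands, and sorts literals before
  groups (so templates print as `T* = A or B or (C and D)`).
* Exhaustive truth tables and the forcing fall-back are capped at 16
  regulators; candidate-rule enumeration at 4.  Both limits raise explicit
  errors rather than degrade.
* Ties everywhere (path order, candidate rules, processing order) break
  lexicographically; identical inputs yield byte-identical `.bnet`, SIF and
  JSON report output.
* Empty statement sets produce an empty model and a zero-count report;
  malformed table rows go to a rejects report with line numbers, never
  silently dropped; self-loops must be explicitly flagged.
* `.bnet` output sanitizes names containing reserved characters
  (whitespace, commas, operators) with a stable documented mapping.

## Known limitations

* The subgraph patterns that mediate indirect implications are decided
  semantically by the LDOI oracle rather than by enumerating the motif
  catalogue of the underlying theory; this is sound and complete for the
  canalizing semantics used here, but a different semantics could require
  the explicit patterns.
* Rule enumeration for manual resolution is exhaustive and hence limited
  to 4 regulators; larger conflicted targets fall back to templates.
* Attractor analysis, update schemes (synchronous/asynchronous), stable
  motifs and multi-level logics are out of scope; the forced-state oracle
  is the only dynamic notion used.
* When several upstream anchors could complete a path, only the declared
  one is used; the package never guesses pathway support.
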