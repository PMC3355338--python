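# Methods

This note records the models, algorithms and design choices behind
`rulemap`, in the order the pipeline uses them.

## Site-graph model and BNGL dialect

A model is a BNGL document: parameters (arithmetic expressions over
`+ - * / ^`, `exp`/`ln`/`log10`, resolved lazily with cycle detection),
molecule type declarations, compartments, seed species, observables,
reaction rules and actions. Patterns are site graphs: molecules carry
named components; a component may carry one internal state and one bond
constraint. Bond syntax: `!n` (explicit bond), `!+` (bound, partner
unspecified), `!?` (unconstrained), a listed component without `!` is
*free*, an unlisted component is unconstrained. `~?` leaves a state
unspecified. Both `begin species` and `begin seed species` are accepted,
as are numeric and `label:` rule prefixes and `@comp:`/`@comp` compartment
tags (normalized to one internal form). Bond labels are local to one
pattern; a label appearing other than exactly twice is a hard error with a
source location. Anything outside this core (functional rate laws, rule
modifiers such as `DeleteMolecules`, unknown action verbs) is preserved
and flagged, never silently dropped; functional rate laws are rejected
only when a simulation actually needs their value.

## Embedding

`embed(pattern, target)` returns the structure-preserving maps of a
pattern into a concrete species or another pattern. Constraints are
*entailed*: a pattern requirement must be guaranteed by the target
(state specified → equal; free → free; `!+` → any bond; labeled bond →
correspondingly paired labeled bond; `!?` → anything). Because concrete
species are fully specified, entailment restricted to them is exactly
concrete matching, so one primitive serves rule application, observable
evaluation and the influence computation. Embeddings differing only by an
automorphism of the pattern are collapsed to one representative
(automorphisms are found by the same matcher in equality mode); this is
the multiplicity convention the statistical factors build on. Identical
same-named sites are interchangeable slots: a pattern mentioning `l` once
may bind either `l` of `Lig(l,l)`.

## Reaction center and context

`compute_delta` maps each reactant-side molecule to a product-side
molecule greedily by name and positional order. When several same-named
molecules make the correspondence ambiguous, all candidate bijections
(capped at 24 per name) are scored and the map minimizing the number of
changed elements wins, ties broken by position, with a warning — a
minimal-change reading chosen here because no convention is universal.
Against the chosen map, each element is classified: bonds created/deleted,
states changed (`from`→`to`), molecules created/deleted form the
**center**; required molecules, unchanged bonds, free/bound constraints
and unchanged states form the **context**. A `!+` reactant bond becoming a
labeled product bond is rejected (the created bond's partner would be
undetermined). Rules classify by their center: bond, state-change,
molecular (creation/deletion only), mixed, or null (empty center).

## Contact map

One node per declaration: molecules own component nodes (one per declared
occurrence, so `Lig(l,l)` owns two), components own state nodes. Each
bond-type center element contributes an edge between the two endpoint
nodes — the *state* node when the rule's reactant constrains that
component's state, else the component node — and edges with identical
endpoints aggregate their rule directions. State-change centers color the
component (`component_state_change`) and both the from- and to-state
nodes (`state_changed`); direction is deliberately not distinguished.
Molecule-level rules get one hub node per rule, linked to every reactant
and product molecule (per-rule hubs keep unrelated rules separate).
Bubble sets project a rule direction's center/context elements onto these
node ids; drawing isocontours is left to export backends, as is layout.
When a rule mentions an identical site fewer times than declared, the
first occurrence's node is annotated and the edge is marked ambiguous.

## Influence graph

Reversible rules are split into forward/reverse nodes first. For ordered
rule directions (r1, r2), every reactant pattern of r2 is matched onto
every reactant pattern of r1 (inhibition) and onto every product pattern
of r1 (activation), with r1's center realized on the respective side:

- **full** — an entailment embedding of the r2 pattern exists whose image
  touches a center element: firing r1 *always* changes the material r2
  matches;
- **partial** — no full embedding, but a consistent overlap (a partial
  molecule/component correspondence with no state or bond-kind conflict)
  touches a center element. Any consistent overlap restricts to a
  single-element one, which makes the existence test linear; the
  brute-force oracle in the test-suite enumerates all overlaps to confirm
  the equivalence. "Maximal consistent overlap touching the center" is
  one reading of an informally specified relation; overlaps touching only
  context yield no edge, since firing cannot change a rate through
  unchanged elements;
- per polarity the strongest relation is kept (full > partial); both
  polarities may coexist on a pair, and opposing polarities never cancel.

Deleted molecules inhibit every rule requiring that molecule — full when
the deleting pattern entails the requirement, else partial. Self-influence
is computed but hidden by default (every binding rule trivially
self-inhibits). The linear arc-diagram order sorts nodes by total degree
descending, ties by declaration order then direction, with forward rules
assigned the upper layer and reverse rules the lower.

## Canonical species labels

Concrete complexes are canonicalized by iterative neighborhood refinement
over molecule colors (initial color: molecule name plus sorted component
signature; refinement: sorted multiset of (site, partner site, partner
color) across bonds), with individualization branching on color ties; the
lexicographically minimal rendering over all branches is the label. Within
a molecule, identical slots order by (name, state, partner position) and
bond ids are assigned in traversal order, so the label is a valid,
re-parseable BNGL species string. The test-suite validates the labels
against an exhaustive permutation oracle on all fixture species up to six
molecules, including symmetric dimers and rings, where refinement alone
cannot discriminate.

## Network generation

Breadth-first: each round applies every rule direction to all species
tuples containing at least one species discovered in the previous round;
products are split into connected components, canonicalized and
deduplicated. Reactions are keyed by (reactant multiset, product multiset,
rule direction) so the NET file can attribute every reaction to its rule.
The rate multiplier is `m/g`: `m` distinct embedding combinations
producing that reaction, `g` the number of permutations of structurally
identical reactant patterns. This is the established network-generation
convention (symmetric dimerization exports `0.5*k`; the symmetric
dissociation exports `k`), preferred over a naive per-ordered-pair count
for NET interoperability; the analytic equilibrium used in the tests,
`K = kf/(2 kr)`, follows from it. Bounds: `max_iter` (default 100) caps
rounds, `max_agg` (default 10) caps molecules per complex; species over
the bound are discarded and the network is flagged truncated with the
reason, which also appears in the NET header. Defaults were chosen so
that toy polymerizing models terminate visibly; they are not tuned to any
particular dataset. Seeds must be concrete; disconnected seed patterns
are split into their components.

## Simulation

ODE: the mass-action right-hand side is `k_j · Π y_i` per reaction
(vectorized for ≤2 reactants), integrated with LSODA on a uniform grid of
`n_steps + 1` points including t = 0 (defaults `atol=1e-9`, `rtol=1e-8`).
SSA: Gillespie direct method on integer copies (non-integral initial
amounts are rounded with a warning), propensities use falling factorials
for repeated reactants — consistent with the `m/g` convention — and state
is recorded at grid times to bound output size; a fixed seed gives
bit-identical reruns. A single abstract "amount" unit is used throughout;
no volume conversion or compartmental rate scaling is applied
(compartments are topological metadata for the contact map).
Observables: `Molecules` weights species by embedding count (a dimer
matching `A()` counts 2), `Species` marks matching species with weight 1.

Actions run in order and thread state: simulations continue from the
previous final concentrations; `setParameter`/`setConcentration` mutate
between runs; each simulation journals `model.bngl`, `run.log`,
`model.net`, `model.gdat`, `model.cdat` into a `<model>_<stamp>`
directory. Parameter scans run one journaled simulation per value and
tabulate final observables; the input model object and file are never
mutated.

## Fixtures and the random model generator

The Lyn fixture is the reduced ligand/receptor/kinase model: `Lig(l,l)`,
`Rec(a,b)`, `Lyn(U,SH2)`, ligand binding and crosslinking plus the two
Lyn-binding rules in correct (free-other-site context) or incorrect
(context dropped) form. Only the Lyn rules are fixed by the exercise; the
ligand rules are a reconstruction and all rate constants are arbitrary
unit values, so the fixture exercises structure, not kinetics. The
early-EGFR fixture is a reconstruction of the published 23-rule early
EGFR scheme (ligand binding restricted to monomers, dimerization of
ligand-bound receptors, transphosphorylation in dimers, dephosphorylation
of unprotected sites, Grb2/Shc/Sos recruitment on membrane and in
cytosol); its reachable network — 48 receptor monomer states, 300
unordered dimer pairs and 8 cytosolic species, 356 in all, with 3749
unidirectional reactions — is a structural property independent of the
rate values, which are nominal.

`random_model` emits seed-deterministic, always-valid models: random
molecule types (with occasional identical sites), concrete seeds, and a
weighted mix of bond, state-change and molecular rules whose context is
mirrored exactly across rule sides. It generates *well-formed* models by
construction; it does not emulate the error modes of hand-written files
(dangling bonds, undeclared names), which the parser tests cover with
explicit malformed inputs. Passing property tests on this corpus
therefore demonstrates algorithmic correctness on valid models, not
robustness to arbitrary real-world files beyond the error paths tested
directly.

## Problem sizes and numerical tolerances

The test-suite and acceptance script run at desk scale by design: random
models with ≤4 rules and ≤3 molecule types against exhaustive oracles
(500 models in the acceptance run), canonicalization oracles up to 6
molecules, SSA accuracy at 10⁴ initial copies × 100 replicates, networks
up to the 356-species EGFR reconstruction. Closed-form comparisons use
tight integrator settings (`atol=1e-12`, `rtol=1e-10`) and assert 10⁻⁶
relative agreement; the SSA mean is required to stay within 3 standard
errors of the ODE trajectory.

## Known limitations

- Functional rate laws (`Sat`, `MM`, global functions) parse but cannot
  be simulated; `DeleteMolecules` semantics (deleting a molecule from a
  retained complex) are not implemented — whole-pattern deletion is.
- Partial-match influence is one formalization of an informal notion;
  alternatives (e.g. requiring minimum overlap sizes) would change
  partial edges only.
- The canonical labeler is exact but exponential in the worst case; it is
  intended for complexes of tens of molecules, not polymers of thousands.
- No network-free simulation: models whose networks do not close under
  the bounds can be generated only in truncated form.
- Compartments carry no kinetic meaning (no volume scaling of rates).
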