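# rulemap

A workbench for **rule-based models** of cell-signaling biochemistry.
Instead of enumerating every chemical species, a rule-based model declares
molecules with binding sites and internal states, and local graph-rewriting
rules over them (BioNetGen language, BNGL). `rulemap` parses such models
and provides the static analyses and simulation machinery a modeler needs
to build, debug and run them:

- **BNGL I/O** — parser/serializer for the BNGL block format plus the
  NET (reaction network) and GDAT/CDAT (time series) result conventions;
- **contact maps** — the one-node-per-declaration summary graph of
  molecules, sites, states, bond edges and hub nodes, with per-rule
  **reaction center/context** node sets ("bubble sets") that make
  missing-context rule errors visible;
- **influence graphs** — directed {full, partial} × {activation,
  inhibition} relations between unidirectional rules, computed by matching
  reactant patterns against each other's reactants (inhibition) and
  products (activation) through the rules' reaction centers;
- **network generation** — bounded breadth-first rule application with
  canonical species labeling, BioNetGen-convention statistical factors,
  and truncation flags for polymerizing models;
- **simulation** — mass-action ODE (stiff-capable) and Gillespie SSA over
  the generated network, observable evaluation, run journaling and
  parameter scans;
- **exports** — GraphML / DOT / JSON for every graph, and a thin
  `rulemap` CLI.

The intended users are systems-biology modelers and tool builders who want
these analyses as a library (see `examples/`) or from the shell.

## The core ideas

For a rule like the low-affinity Lyn-receptor binding rule

```
Rec(b) + Lyn(SH2,U) <-> Rec(b!1).Lyn(SH2!1,U)
```

the **reaction center** is the created bond `Rec.b–Lyn.SH2`; the
**reaction context** is everything required but unchanged — here the two
molecules and the *free U site* of Lyn. Dropping `U` from the rule leaves
the contact map unchanged but silently allows one Lyn to bridge two
receptors, producing an unbounded polymer at network-generation time.
`rulemap` surfaces this statically: the context bubble of the correct rule
contains the free-site element, the incorrect one does not.

Rule influence is computed in two steps: match every reactant pattern of
rule 2 onto every reactant pattern of rule 1 — a match whose image touches
rule 1's reaction center is an inhibition (full if every constraint of the
pattern is entailed, partial if only a consistent overlap exists) — and
symmetrically onto rule 1's product patterns for activation; per polarity
the strongest relation wins.

Generated reactions follow the mass-action convention: each reaction's
rate multiplier is `m/g`, where `m` counts distinct embedding combinations
(up to pattern automorphism) and `g` the permutations of identical
reactant patterns — symmetric dimerization `A(a)+A(a) -> A(a!1).A(a!1)`
with rate `k` exports `0.5*k`, so its equilibrium constant is
`[A.A]/[A]^2 = kf/(2 kr)`.

## Worked example

```python
from rulemap import build_contact_map, bubble_sets, generate_network
from rulemap.fixtures import lyn_fixture
from rulemap.model import RuleDir

good = build_contact_map(lyn_fixture(correct=True))
bad  = build_contact_map(lyn_fixture(correct=False))
print(set(good.nodes()) == set(bad.nodes()))        # True
g = bubble_sets(good, RuleDir("LynSH2", "forward"))
b = bubble_sets(bad,  RuleDir("LynSH2", "forward"))
print(g.context_nodes - b.context_nodes)            # {'C:Lyn.U#0'}

net = generate_network(lyn_fixture(correct=False), max_iter=30, max_agg=5)
print(len(net.species), net.truncation_reason)      # 20 max_agg
```

The two maps are topologically identical (`True`); only the bubble context
differs, by exactly the free-U requirement (`{'C:Lyn.U#0'}`); and the
incorrect model's network is truncated at the aggregate bound with 20
species and keeps growing as the bound is raised — the unbounded chain.

On the bundled reconstruction of the early-EGFR signaling model (EGF,
EGFR, Grb2, Shc, Sos; 23 rules):

```python
net = generate_network(rulemap.fixtures.egfr_fixture(), max_iter=50, max_agg=20)
print(len(net.species), len(net.reactions))          # 356 3749
```

356 reachable molecular species connected by 3749 unidirectional
reactions, from 23 rules — the combinatorial complexity that motivates
rule-based specification.

Each script in `examples/` demonstrates one capability and prints what the
numbers mean. The CLI mirrors the library:

```
rulemap validate model.bngl
rulemap contact-map model.bngl --format graphml --out cm.graphml --bubbles
rulemap influence model.bngl --format json
rulemap network model.bngl --max-agg 10 --out model.net
rulemap simulate model.bngl --journal runs/
rulemap scan model.bngl --parameter k --values "0.1;1;10"
```

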