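"""Rule influence graphs: full/partial activation and inhibition.

Nodes are unidirectional rules (reversible rules split into forward and
reverse).  For an ordered pair (r1, r2):

* inhibition — each reactant pattern of r2 is matched onto each reactant
  pattern of r1: a *full* match (every constraint of the r2 pattern is
  entailed by the r1 pattern) whose image touches a reaction-center
  element of r1 means firing r1 always consumes material r2 needs; a
  consistent partial overlap touching the center means it may;
* activation — the same matching of r2 reactant patterns onto r1 *product*
  patterns, with r1's center as realized on the product side.

Per polarity the strongest relation wins (full > partial).  Both
polarities may coexist on a pair.  Self-influence is computed but hidden
unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    BOUND_ANY, FREE, Model, RuleDir, SpeciesPattern, WILD,
)
from .patterns import RuleDelta, compute_delta, embed

Relation = tuple[str, str]       # (polarity, strength)


@dataclass
class SideCenter:
    """Center elements of a rule direction realized on one side's patterns.

    ``slots[pattern_index]`` holds local (molecule, component) slots that
    carry center elements; ``mols[pattern_index]`` holds molecule indices
    created/deleted by the rule.
    """

    slots: dict[int, set] = field(default_factory=dict)
    mols: dict[int, set] = field(default_factory=dict)

    def touches(self, pattern_index: int) -> bool:
        return bool(self.slots.get(pattern_index)
                    or self.mols.get(pattern_index))


def _center_on_side(delta: RuleDelta, side: str) -> SideCenter:
    sc = SideCenter()
    flats = delta.reactant_mols if side == "reactant" else delta.product_mols

    def add_slot(flat_slot):
        if flat_slot is None:
            return
        if isinstance(flat_slot, tuple) and len(flat_slot) == 3 \
                and flat_slot[0] == "new":
            if side != "product":
                return
            pi, mi = delta.product_mols[flat_slot[1]]
            sc.slots.setdefault(pi, set()).add((mi, flat_slot[2]))
            return
        fm, ci = flat_slot
        if side == "reactant":
            pi, mi = delta.reactant_mols[fm]
            sc.slots.setdefault(pi, set()).add((mi, ci))
        else:
            mapped = delta.comp_map.get((fm, ci))
            if mapped is not None:
                pj, cj = mapped
                ppi, pmi = delta.product_mols[pj]
                sc.slots.setdefault(ppi, set()).add((pmi, cj))

    for el in delta.center:
        tag = el[0]
        if tag in ("bond+", "bond-"):
            add_slot(el[1])
            add_slot(el[2])
        elif tag == "state":
            add_slot(el[1])
        elif tag == "mol-" and side == "reactant":
            pi, mi = delta.reactant_mols[el[1]]
            sc.mols.setdefault(pi, set()).add(mi)
        elif tag == "mol+" and side == "product":
            pi, mi = delta.product_mols[el[1]]
            sc.mols.setdefault(pi, set()).add(mi)
    return sc


def _bond_kind_compatible(a, b) -> bool:
    """Symmetric no-conflict test between two pattern bond constraints."""
    if a == WILD or b == WILD:
        return True
    a_bound = a == BOUND_ANY or isinstance(a, int)
    b_bound = b == BOUND_ANY or isinstance(b, int)
    return a_bound == b_bound


def pattern_relation(p2: SpeciesPattern, p1: SpeciesPattern,
                     center_slots: set, center_mols: set) -> str:
    """Relation of a reactant pattern p2 of rule 2 to a pattern p1 of
    rule 1 whose center carriers within p1 are given.

    Returns ``"full"``, ``"partial"`` or ``"none"``.
    """
    if not center_slots and not center_mols:
        return "none"
    # full: an entailment embedding of p2 into p1 touching the center
    for e in embed(p2, p1):
        image_mols = set(e.mol_map)
        image_slots = set(e.comp_map.values())
        if image_slots & center_slots or image_mols & center_mols:
            return "full"
    # partial: a consistent single-element overlap touching the center
    # suffices (any consistent overlap restricts to one)
    for m2 in p2.molecules:
        for mi1, m1 in enumerate(p1.molecules):
            if m1.name != m2.name:
                continue
            if mi1 in center_mols:
                return "partial"
            for c2 in m2.components:
                for ci1, c1 in enumerate(m1.components):
                    if (mi1, ci1) not in center_slots:
                        continue
                    if c1.name != c2.name:
                        continue
                    if c2.state is not None and c1.state is not None \
                            and c2.state != c1.state:
                        continue
                    if not _bond_kind_compatible(c2.bond, c1.bond):
                        continue
                    return "partial"
    return "none"


def rule_influence(rule1, dir1: str, rule2, dir2: str,
                   delta1: RuleDelta | None = None) -> set[Relation]:
    """Influence of firing (rule1, dir1) on the rate of (rule2, dir2)."""
    delta1 = delta1 or compute_delta(rule1, dir1)
    reactants1, products1 = rule1.sides(dir1)
    reactants2, _products2 = rule2.sides(dir2)
    center_r = _center_on_side(delta1, "reactant")
    center_p = _center_on_side(delta1, "product")

    relations: set[Relation] = set()
    for polarity, side_patterns, center in (
            ("inhibition", reactants1, center_r),
            ("activation", products1, center_p)):
        best = None
        for p2 in reactants2:
            for i1, p1 in enumerate(side_patterns):
                if not center.touches(i1):
                    continue
                rel = pattern_relation(
                    p2, p1, center.slots.get(i1, set()),
                    center.mols.get(i1, set()))
                if rel == "full":
                    best = "full"
                    break
                if rel == "partial" and best is None:
                    best = "partial"
            if best == "full":
                break
        if best is not None:
            relations.add((polarity, best))
    return relations


@dataclass
class InfluenceGraph:
    nodes: list[RuleDir] = field(default_factory=list)
    # (source, target, polarity, strength)
    edges: list[tuple[RuleDir, RuleDir, str, str]] = field(
        default_factory=list)

    def components(self) -> list[set[RuleDir]]:
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for src, dst, _pol, _st in self.edges:
            g.add_edge(src, dst)
        return [set(c) for c in nx.connected_components(g)]

    def degree(self, node: RuleDir) -> int:
        return sum(1 for s, d, _p, _t in self.edges if s == node or
                   d == node)

    def to_networkx(self):
        import networkx as nx
        g = nx.MultiDiGraph()
        order, layer = linear_order(self)
        idx = {n: i for i, n in enumerate(order)}
        for n in self.nodes:
            g.add_node(str(n), rule=n.label, direction=n.direction,
                       layer=layer[n], order=idx[n], degree=self.degree(n))
        for src, dst, pol, strength in self.edges:
            g.add_edge(str(src), str(dst), polarity=pol, strength=strength,
                       style="solid" if strength == "full" else "dashed",
                       color="green" if pol == "activation" else "magenta")
        return g


def build_influence_graph(model: Model,
                          include_self: bool = False) -> InfluenceGraph:
    """Influence edges over all ordered pairs of rule directions.

    Per pair and polarity only the strongest relation is kept
    (full > partial); self-loops are dropped unless ``include_self``.
    """
    graph = InfluenceGraph(nodes=model.rule_directions())
    deltas = {rdir: compute_delta(model.rule(rdir.label), rdir.direction)
              for rdir in graph.nodes}
    for r1 in graph.nodes:
        rule1 = model.rule(r1.label)
        for r2 in graph.nodes:
            if r1 == r2 and not include_self:
                continue
            rule2 = model.rule(r2.label)
            for polarity, strength in sorted(rule_influence(
                    rule1, r1.direction, rule2, r2.direction, deltas[r1])):
                graph.edges.append((r1, r2, polarity, strength))
    return graph


def linear_order(graph: InfluenceGraph
                 ) -> tuple[list[RuleDir], dict[RuleDir, str]]:
    """Arc-diagram ordering: degree-descending, ties by declaration order
    then direction (forward first); forward rules go to the upper layer."""
    decl = {n: i for i, n in enumerate(graph.nodes)}
    order = sorted(
        graph.nodes,
        key=lambda n: (-graph.degree(n), decl[n],
                       0 if n.direction == "forward" else 1))
    layer = {n: ("upper" if n.direction == "forward" else "lower")
             for n in graph.nodes}
    return order, layer
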