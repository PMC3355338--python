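"""Contact map construction.

The contact map is the one-node-per-declaration summary of a model:
molecule nodes own component nodes (one per declared occurrence, so
``Lig(l,l)`` owns two ``l`` nodes), component nodes own state nodes, and
rules annotate the graph — bond rules as edges between component (or,
when a reactant constrains the state, state) nodes, state-change rules as
node classes, molecule-level rules as hub nodes linked to the molecules
they touch.  Per-rule center/context node sets ("bubble sets") are
computed here; drawing them is left to export backends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import BnglError, Diagnostic, Model, RuleDir
from .patterns import RuleDelta, classify_rule, compute_delta


# --- node id helpers -------------------------------------------------------


def molecule_id(name: str) -> str:
    return f"M:{name}"


def component_id(mol: str, comp: str, occ: int = 0) -> str:
    return f"C:{mol}.{comp}#{occ}"


def state_id(mol: str, comp: str, occ: int, state: str) -> str:
    return f"S:{mol}.{comp}#{occ}~{state}"


def hub_id(rule_label: str) -> str:
    return f"H:{rule_label}"


@dataclass
class BubbleAnnotation:
    """Center/context contact-map node sets for one rule direction."""

    rule: RuleDir
    center_nodes: set[str] = field(default_factory=set)
    context_nodes: set[str] = field(default_factory=set)


@dataclass
class ContactMap:
    molecule_nodes: list[str] = field(default_factory=list)
    component_nodes: dict[str, str] = field(default_factory=dict)  # id->owner
    state_nodes: dict[str, str] = field(default_factory=dict)      # id->owner
    hub_nodes: dict[str, list[str]] = field(default_factory=dict)  # id->mols
    # frozenset of endpoint node ids -> ordered rule directions
    bond_edges: dict[frozenset, list[RuleDir]] = field(default_factory=dict)
    node_class: dict[str, str] = field(default_factory=dict)
    compartment_of: dict[str, Optional[str]] = field(default_factory=dict)
    bubbles: dict[RuleDir, BubbleAnnotation] = field(default_factory=dict)
    ambiguous_edges: set[frozenset] = field(default_factory=set)

    def nodes(self) -> list[str]:
        return (self.molecule_nodes + list(self.component_nodes)
                + list(self.state_nodes) + list(self.hub_nodes))

    def to_networkx(self, show_states: bool = True):
        import networkx as nx
        g = nx.Graph()
        for n in self.molecule_nodes:
            g.add_node(n, kind="molecule", label=n[2:],
                       node_class="molecule",
                       compartment=self.compartment_of.get(n) or "")
        for n, owner in self.component_nodes.items():
            g.add_node(n, kind="component", label=n.split(".")[1],
                       node_class=self.node_class.get(n, ""), owner=owner)
            g.add_edge(owner, n, kind="part_of")
        if show_states:
            for n, owner in self.state_nodes.items():
                g.add_node(n, kind="state", label=n.split("~")[-1],
                           node_class=self.node_class.get(n, ""), owner=owner)
                g.add_edge(owner, n, kind="part_of")
        for n, mols in self.hub_nodes.items():
            g.add_node(n, kind="hub", label=n[2:], node_class="hub")
            for mid in mols:
                g.add_edge(n, mid, kind="hub")
        for ends, rules in self.bond_edges.items():
            pair = sorted(ends)
            a, b = (pair[0], pair[-1])
            if not show_states:
                a, b = self._demote(a), self._demote(b)
            rule_list = [str(r) for r in rules]
            if g.has_edge(a, b) and g[a][b].get("kind") == "bond":
                merged = g[a][b]["rules"].split(";") + rule_list
                g[a][b]["rules"] = ";".join(sorted(set(merged)))
            else:
                g.add_edge(a, b, kind="bond", rules=";".join(rule_list))
        return g

    def _demote(self, node: str) -> str:
        """State node -> its owning component node (for show_states=False)."""
        if node.startswith("S:"):
            return self.state_nodes[node]
        return node


# --- construction ----------------------------------------------------------


def _decl_occurrence(model: Model, mol_name: str, comp_name: str,
                     mention_index: int) -> int:
    """Declared occurrence index for the k-th mention of a component name."""
    mt = model.molecule_type(mol_name)
    if mt is None:
        return mention_index
    n = sum(1 for cname, _states in mt.components if cname == comp_name)
    return min(mention_index, max(n - 1, 0))


def _slot_node(model: Model, patterns, flat_mols, slot,
               product_patterns=None, product_flats=None,
               use_state: bool = True) -> tuple[str, Optional[str], bool]:
    """Contact-map endpoint for a rule slot.

    Returns (node id, molecule name, ambiguous) where the node is the state
    node when the slot's pattern constrains a state (and ``use_state``),
    otherwise the component node.
    """
    if isinstance(slot, tuple) and len(slot) == 3 and slot[0] == "new":
        pi, mi = product_flats[slot[1]]
        mol = product_patterns[pi].molecules[mi]
        ci = slot[2]
    else:
        fm, ci = slot
        pi, mi = flat_mols[fm]
        mol = patterns[pi].molecules[mi]
    comp = mol.components[ci]
    mention = sum(1 for c in mol.components[:ci] if c.name == comp.name)
    occ = _decl_occurrence(model, mol.name, comp.name, mention)
    mt = model.molecule_type(mol.name)
    n_decl = 0
    if mt is not None:
        n_decl = sum(1 for c, _s in mt.components if c == comp.name)
    n_mention = sum(1 for c in mol.components if c.name == comp.name)
    ambiguous = n_decl > n_mention  # fewer mentions than declared slots
    if use_state and comp.state is not None:
        return (state_id(mol.name, comp.name, occ, comp.state), mol.name,
                ambiguous)
    return component_id(mol.name, comp.name, occ), mol.name, ambiguous


def build_contact_map(model: Model) -> ContactMap:
    """Construct the contact map of a validated model."""
    cmap = ContactMap()
    for mt in model.molecule_types:
        mid = molecule_id(mt.name)
        cmap.molecule_nodes.append(mid)
        occ_count: dict[str, int] = {}
        for cname, states in mt.components:
            occ = occ_count.get(cname, 0)
            occ_count[cname] = occ + 1
            cid = component_id(mt.name, cname, occ)
            cmap.component_nodes[cid] = mid
            cmap.node_class[cid] = ("component_no_state" if not states
                                    else "component_state_no_change")
            for s in states:
                sid = state_id(mt.name, cname, occ, s)
                cmap.state_nodes[sid] = cid
                cmap.node_class[sid] = "state_unchanged"

    # compartment assignment: first tag seen in seeds, then rules
    comp_seen: dict[str, str] = {}
    for pat, _amt in model.seed_species:
        for mol in pat.molecules:
            if mol.compartment and mol.name not in comp_seen:
                comp_seen[mol.name] = mol.compartment
    for rule in model.rules:
        for pat in rule.reactants + rule.products:
            for mol in pat.molecules:
                if mol.compartment and mol.name not in comp_seen:
                    comp_seen[mol.name] = mol.compartment
    for mt in model.molecule_types:
        cmap.compartment_of[molecule_id(mt.name)] = comp_seen.get(mt.name)

    for rdir in model.rule_directions():
        rule = model.rule(rdir.label)
        delta = compute_delta(rule, rdir.direction)
        category = classify_rule(rule, rdir.direction, delta)
        reactants, products = rule.sides(rdir.direction)
        r_flat = delta.reactant_mols
        p_flat = delta.product_mols

        for el in delta.center:
            if el[0] in ("bond+", "bond-"):
                ends = []
                amb = False
                for slot in (el[1], el[2]):
                    if slot is None:
                        continue
                    node, _mname, a = _slot_node(
                        model, reactants, r_flat, slot, products, p_flat)
                    ends.append(node)
                    amb = amb or a
                key = frozenset(ends)
                cmap.bond_edges.setdefault(key, [])
                if rdir not in cmap.bond_edges[key]:
                    cmap.bond_edges[key].append(rdir)
                if amb:
                    cmap.ambiguous_edges.add(key)
            elif el[0] == "state":
                _tag, slot, s_from, s_to = el
                node, mname, _a = _slot_node(
                    model, reactants, r_flat, slot, products, p_flat,
                    use_state=False)
                cmap.node_class[node] = "component_state_change"
                fm, ci = slot
                pi, mi = r_flat[fm]
                comp = reactants[pi].molecules[mi].components[ci]
                mention = sum(1 for c in reactants[pi].molecules[mi]
                              .components[:ci] if c.name == comp.name)
                occ = _decl_occurrence(model, mname, comp.name, mention)
                for s in (s_from, s_to):
                    if s is None:
                        continue
                    sid = state_id(mname, comp.name, occ, s)
                    if sid in cmap.state_nodes:
                        cmap.node_class[sid] = "state_changed"

        if category in ("molecular_rule", "mixed") and (
                delta.created or delta.deleted):
            hid = hub_id(rdir.label)
            mols = []
            for pat in reactants + products:
                for mol in pat.molecules:
                    mid = molecule_id(mol.name)
                    if mid not in mols:
                        mols.append(mid)
            if hid in cmap.hub_nodes:
                for mid in mols:
                    if mid not in cmap.hub_nodes[hid]:
                        cmap.hub_nodes[hid].append(mid)
            else:
                cmap.hub_nodes[hid] = mols

        cmap.bubbles[rdir] = _project_bubble(model, rdir, delta, reactants,
                                             products)
    return cmap


def _project_bubble(model: Model, rdir: RuleDir, delta: RuleDelta,
                    reactants, products) -> BubbleAnnotation:
    """Project center/context rule elements onto contact-map node ids."""
    r_flat, p_flat = delta.reactant_mols, delta.product_mols
    ann = BubbleAnnotation(rdir)

    def mol_node(flat_idx, flats, patterns):
        pi, mi = flats[flat_idx]
        return molecule_id(patterns[pi].molecules[mi].name)

    for el in delta.center:
        tag = el[0]
        if tag in ("bond+", "bond-"):
            for slot in (el[1], el[2]):
                if slot is None:
                    continue
                node, _m, _a = _slot_node(model, reactants, r_flat, slot,
                                          products, p_flat)
                ann.center_nodes.add(node)
        elif tag == "state":
            _t, slot, s_from, s_to = el
            node, mname, _a = _slot_node(model, reactants, r_flat, slot,
                                         products, p_flat, use_state=False)
            ann.center_nodes.add(node)
            fm, ci = slot
            pi, mi = r_flat[fm]
            comp = reactants[pi].molecules[mi].components[ci]
            mention = sum(1 for c in reactants[pi].molecules[mi]
                          .components[:ci] if c.name == comp.name)
            occ = _decl_occurrence(model, mname, comp.name, mention)
            for s in (s_from, s_to):
                if s is not None:
                    ann.center_nodes.add(state_id(mname, comp.name, occ, s))
        elif tag == "mol-":
            ann.center_nodes.add(mol_node(el[1], r_flat, reactants))
        elif tag == "mol+":
            ann.center_nodes.add(mol_node(el[1], p_flat, products))

    for el in delta.context:
        tag = el[0]
        if tag == "mol":
            ann.context_nodes.add(mol_node(el[1], r_flat, reactants))
        elif tag in ("free", "bound"):
            node, _m, _a = _slot_node(model, reactants, r_flat, el[1],
                                      use_state=False)
            ann.context_nodes.add(node)
        elif tag == "bond=":
            for slot in (el[1], el[2]):
                if slot is None:
                    continue
                node, _m, _a = _slot_node(model, reactants, r_flat, slot,
                                          use_state=False)
                ann.context_nodes.add(node)
        elif tag == "state=":
            _t, slot, s = el
            fm, ci = slot
            pi, mi = r_flat[fm]
            mol = reactants[pi].molecules[mi]
            comp = mol.components[ci]
            mention = sum(1 for c in mol.components[:ci]
                          if c.name == comp.name)
            occ = _decl_occurrence(model, mol.name, comp.name, mention)
            sid = state_id(mol.name, comp.name, occ, s)
            ann.context_nodes.add(
                sid if sid in _declared_states(model, mol.name)
                else component_id(mol.name, comp.name, occ))
    ann.context_nodes -= ann.center_nodes
    return ann


def _declared_states(model: Model, mol_name: str) -> set[str]:
    mt = model.molecule_type(mol_name)
    out = set()
    if mt is None:
        return out
    occ_count: dict[str, int] = {}
    for cname, states in mt.components:
        occ = occ_count.get(cname, 0)
        occ_count[cname] = occ + 1
        for s in states:
            out.add(state_id(mol_name, cname, occ, s))
    return out


# --- queries ---------------------------------------------------------------


def rules_for_edge(cmap: ContactMap, edge) -> list[RuleDir]:
    """Declaration-ordered rule directions contributing to a bond edge."""
    key = frozenset(edge) if not isinstance(edge, frozenset) else edge
    if key not in cmap.bond_edges:
        raise BnglError(Diagnostic("error", f"unknown contact-map edge "
                                   f"{sorted(key)}"))
    return list(cmap.bond_edges[key])


def rules_for_state(cmap: ContactMap, state_node: str,
                    model: Model) -> list[RuleDir]:
    """Rule directions whose state-change center touches a state node."""
    if state_node not in cmap.state_nodes:
        raise BnglError(Diagnostic(
            "error", f"unknown state node {state_node!r}"))
    out = []
    for rdir in model.rule_directions():
        rule = model.rule(rdir.label)
        delta = compute_delta(rule, rdir.direction)
        reactants, _products = rule.sides(rdir.direction)
        r_flat = delta.reactant_mols
        for el in delta.center:
            if el[0] != "state":
                continue
            _t, slot, s_from, s_to = el
            fm, ci = slot
            pi, mi = r_flat[fm]
            mol = reactants[pi].molecules[mi]
            comp = mol.components[ci]
            mention = sum(1 for c in mol.components[:ci]
                          if c.name == comp.name)
            occ = _decl_occurrence(model, mol.name, comp.name, mention)
            for s in (s_from, s_to):
                if s is not None and state_id(mol.name, comp.name, occ,
                                              s) == state_node:
                    if rdir not in out:
                        out.append(rdir)
    return out


def bubble_sets(cmap: ContactMap, rdir: RuleDir) -> BubbleAnnotation:
    if rdir not in cmap.bubbles:
        raise BnglError(Diagnostic(
            "error", f"rule direction {rdir} not in contact map"))
    return cmap.bubbles[rdir]


# --- compartments ----------------------------------------------------------


@dataclass
class CompartmentTree:
    depth: dict[str, int] = field(default_factory=dict)
    children: dict[Optional[str], list[str]] = field(default_factory=dict)
    members: dict[str, list[str]] = field(default_factory=dict)


def compartment_hierarchy(model: Model) -> CompartmentTree:
    """Depth-annotated compartment forest plus molecule membership."""
    tree = CompartmentTree()
    names = {c.name for c in model.compartments}
    for c in model.compartments:
        if c.parent is not None and c.parent not in names:
            raise BnglError(Diagnostic(
                "error", f"unknown parent compartment {c.parent!r}", c.line))
    parent = {c.name: c.parent for c in model.compartments}
    for c in model.compartments:
        depth, cur, hops = 0, c.parent, 0
        while cur is not None:
            depth += 1
            cur = parent[cur]
            hops += 1
            if hops > len(parent):
                raise BnglError(Diagnostic(
                    "error", f"compartment parent cycle at {c.name}", c.line))
        tree.depth[c.name] = depth
        tree.children.setdefault(c.parent, []).append(c.name)
        tree.members.setdefault(c.name, [])
    cmap = build_contact_map(model)
    for mid, comp in cmap.compartment_of.items():
        if comp is not None and comp in tree.members:
            tree.members[comp].append(mid)
    return tree


def detect_orphans(model: Model) -> tuple[list[str], list[RuleDir]]:
    """Molecules with no bond/hub edge; rules with no influence edge."""
    from .influence import build_influence_graph
    cmap = build_contact_map(model)
    connected: set[str] = set()
    for ends in cmap.bond_edges:
        for node in ends:
            if node.startswith("S:"):
                node = cmap.state_nodes[node]
            connected.add(cmap.component_nodes[node])
    for mols in cmap.hub_nodes.values():
        connected.update(mols)
    orphan_mols = [m for m in cmap.molecule_nodes if m not in connected]

    ig = build_influence_graph(model)
    touched: set[RuleDir] = set()
    for src, dst, _pol, _st in ig.edges:
        touched.add(src)
        touched.add(dst)
    orphan_rules = [n for n in ig.nodes if n not in touched]
    return orphan_mols, orphan_rules
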