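"""Bounded reaction-network generation by iterative rule application.

Rules are applied breadth-first to the seed species; product complexes are
canonicalized and deduplicated, so generation reaches a fixpoint exactly
when the model's reachable species set is finite.  ``max_iter`` bounds the
number of rounds and ``max_agg`` the number of molecules per complex;
hitting either bound sets the network's ``truncated`` flag.

Rate-constant convention follows BioNetGen: each generated reaction carries
a multiplier ``m / g`` where ``m`` counts the distinct embedding
combinations (collapsed over pattern automorphisms) producing the same
reactant/product pair and ``g`` counts permutations of identical reactant
patterns.  Symmetric dimerization ``A(a)+A(a) -> A(a!1).A(a!1)`` with rate
``k`` therefore exports ``0.5*k``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

from . import expr as _expr
from .model import (
    BnglError, Diagnostic, FREE, Model, MoleculePattern, RuleDir,
    SpeciesPattern,
)
from .patterns import (
    RuleDelta, canonical_form, compute_delta, embed, is_concrete,
)
from .serializer import pattern_to_str


@dataclass
class NetSpecies:
    index: int                        # 1-based, BioNetGen convention
    pattern: SpeciesPattern
    canonical: str
    initial_expr: str = "0"

    def __str__(self) -> str:
        return self.canonical


@dataclass
class Reaction:
    index: int
    reactants: tuple[int, ...]        # species indices (1-based), sorted
    products: tuple[int, ...]
    rate_expr: str
    factor: float
    rule: RuleDir

    def rate_text(self) -> str:
        if self.factor == 1:
            return self.rate_expr
        return f"{_fmt_factor(self.factor)}*({self.rate_expr})"


def _fmt_factor(f: float) -> str:
    return f"{f:g}"


@dataclass
class ReactionNetwork:
    species: list[NetSpecies] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    observable_groups: dict[str, list[tuple[int, float]]] = field(
        default_factory=dict)
    parameters: dict[str, str] = field(default_factory=dict)
    truncated: bool = False
    truncation_reason: Optional[str] = None

    def initial_amounts(self, overrides=None) -> list[float]:
        return [_expr.evaluate(s.initial_expr, self.parameters, overrides)
                for s in self.species]

    def rate_constants(self, overrides=None) -> list[float]:
        out = []
        for r in self.reactions:
            try:
                k = _expr.evaluate(r.rate_expr, self.parameters, overrides)
            except BnglError as e:
                raise BnglError(Diagnostic(
                    "error", f"rate law {r.rate_expr!r} of reaction "
                    f"{r.index} is not a mass-action expression "
                    f"({e.diagnostics[0].message}); functional rate laws "
                    "are not simulatable")) from e
            if k < 0:
                raise BnglError(Diagnostic(
                    "error", f"negative rate for reaction {r.index}"))
            out.append(k * r.factor)
        return out


# ---------------------------------------------------------------------------


class _RuleApplicator:
    """Compiled form of one rule direction."""

    def __init__(self, rule, direction: str, model: Model):
        self.rule = rule
        self.direction = direction
        self.rdir = RuleDir(rule.label, direction)
        self.delta: RuleDelta = compute_delta(rule, direction)
        self.patterns, self.product_patterns = rule.sides(direction)
        self.rate_expr = rule.rate(direction)
        # symmetry: permutations of identical reactant patterns
        self.g = _pattern_list_symmetry(self.patterns)
        # created molecules must be concrete
        for j in self.delta.created:
            pi, mi = self.delta.product_mols[j]
            mol = self.product_patterns[pi].molecules[mi]
            probe = SpeciesPattern([mol.clone()])
            if not is_concrete(probe, model.molecule_types):
                raise BnglError(Diagnostic(
                    "error", f"rule {rule.label} creates a non-concrete "
                    f"molecule {mol.name}", rule.line))


def _pattern_list_symmetry(patterns: list[SpeciesPattern]) -> int:
    keys = [_pattern_struct_key(p) for p in patterns]
    g = 0
    for perm in itertools.permutations(range(len(patterns))):
        if all(keys[i] == keys[perm[i]] for i in range(len(patterns))):
            # require exact isomorphism, not just equal key
            if all(_exact_iso(patterns[i], patterns[perm[i]])
                   for i in range(len(patterns))):
                g += 1
    return max(g, 1)


def _pattern_struct_key(p: SpeciesPattern) -> tuple:
    return tuple(sorted((m.name, len(m.components)) for m in p.molecules))


def _exact_iso(a: SpeciesPattern, b: SpeciesPattern) -> bool:
    if a is b:
        return True
    return len(embed(a, b, exact=True, collapse=False)) > 0


def _instantiate(species_list: list[SpeciesPattern]) -> SpeciesPattern:
    """Disjoint union of concrete complexes with bond labels re-numbered."""
    union = SpeciesPattern()
    next_label = itertools.count(1)
    for sp in species_list:
        relabel: dict[int, int] = {}
        for mol in sp.molecules:
            m = mol.clone()
            for comp in m.components:
                if isinstance(comp.bond, int):
                    if comp.bond not in relabel:
                        relabel[comp.bond] = next(next_label)
                    comp.bond = relabel[comp.bond]
            union.molecules.append(m)
    return union


def apply_rule_instance(app: _RuleApplicator,
                        species_tuple: list[SpeciesPattern],
                        embeddings: list) -> list[SpeciesPattern]:
    """Rewrite a tuple of reactant complexes along chosen embeddings.

    Returns the connected product complexes (concrete species patterns).
    """
    delta = app.delta
    union = _instantiate(species_tuple)
    # offset of each tuple position's molecules in the union
    offsets = []
    off = 0
    for sp in species_tuple:
        offsets.append(off)
        off += len(sp.molecules)

    # map rule reactant flat molecule -> union molecule index
    mol_image: dict[int, int] = {}
    comp_image: dict[tuple[int, int], tuple[int, int]] = {}
    for flat_idx, (pi, mi) in enumerate(delta.reactant_mols):
        e = embeddings[pi]
        tmol = e.mol_map[mi]
        mol_image[flat_idx] = offsets[pi] + tmol
    for (fm, ci) in _reactant_slots(delta):
        pi, mi = delta.reactant_mols[fm]
        e = embeddings[pi]
        ti, tj = e.comp_map[(mi, ci)]
        comp_image[(fm, ci)] = (offsets[pi] + ti, tj)

    partner = union.bond_partner()
    next_label = 1 + max(
        [b for _mi, _ci, c in union.slots()
         if isinstance((b := c.bond), int)] or [0])

    def ucomp(uslot):
        return union.molecules[uslot[0]].components[uslot[1]]

    created_mol_index: dict[int, int] = {}

    def resolve(slot):
        # slot is either a reactant slot or ("new", prod_flat_idx, comp_idx)
        if isinstance(slot, tuple) and len(slot) == 3 and slot[0] == "new":
            return (created_mol_index[slot[1]], slot[2])
        return comp_image[slot]

    # 1. instantiate created molecules
    for j in delta.created:
        pi, mi = delta.product_mols[j]
        mol = app.product_patterns[pi].molecules[mi].clone()
        for comp in mol.components:
            if isinstance(comp.bond, int):
                comp.bond = FREE     # created bonds re-added below
        created_mol_index[j] = len(union.molecules)
        union.molecules.append(mol)

    # 2. state changes
    for el in delta.center:
        if el[0] == "state":
            _t, slot, _from, to = el
            ucomp(resolve(slot)).state = to

    # 3. delete bonds
    for el in delta.center:
        if el[0] == "bond-":
            a = resolve(el[1])
            b = resolve(el[2]) if el[2] is not None else partner.get(a)
            ucomp(a).bond = FREE
            if b is not None:
                ucomp(b).bond = FREE

    # 4. delete molecules (freeing their partners)
    deleted_union = sorted((mol_image[i] for i in delta.deleted),
                           reverse=True)
    if deleted_union:
        partner = union.bond_partner()
        for umi in deleted_union:
            for ci in range(len(union.molecules[umi].components)):
                p = partner.get((umi, ci))
                if p is not None and p[0] not in deleted_union:
                    ucomp(p).bond = FREE
        for umi in deleted_union:
            del union.molecules[umi]
        # re-index comp/mol images after deletion
        shift = {}
        k = 0
        total = len(union.molecules) + len(deleted_union)
        for old in range(total):
            if old in deleted_union:
                continue
            shift[old] = k
            k += 1
        comp_image = {s: (shift[u[0]], u[1]) for s, u in comp_image.items()
                      if u[0] in shift}
        created_mol_index = {j: shift[u]
                             for j, u in created_mol_index.items()}

    # 5. create bonds
    for el in delta.center:
        if el[0] == "bond+":
            try:
                a = resolve(el[1])
                b = resolve(el[2])
            except KeyError:
                continue   # endpoint on deleted material: malformed rule
            ucomp(a).bond = next_label
            ucomp(b).bond = next_label
            next_label += 1

    # 6. split into connected components
    return _split_components(union)


def _reactant_slots(delta: RuleDelta):
    slots = set()
    for el in itertools.chain(delta.center, delta.context):
        for part in el[1:]:
            if (isinstance(part, tuple) and len(part) == 2
                    and isinstance(part[0], int)):
                slots.add(part)
    # also every slot that has a component correspondence (for bond ops)
    slots.update(delta.comp_map.keys())
    return slots


def _split_components(union: SpeciesPattern) -> list[SpeciesPattern]:
    n = len(union.molecules)
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for ends in union.bonds().values():
        if len(ends) == 2:
            (a, _), (b, _) = ends
            adj[a].add(b)
            adj[b].add(a)
    seen: set[int] = set()
    out = []
    for start in range(n):
        if start in seen:
            continue
        comp = []
        stack = [start]
        seen.add(start)
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        out.append(SpeciesPattern(
            [union.molecules[i] for i in sorted(comp)]))
    return out


# ---------------------------------------------------------------------------


def generate_network(model: Model, max_iter: int = 100,
                     max_agg: int = 10) -> ReactionNetwork:
    """Apply every rule direction iteratively to the seed species.

    Stops at the reachability fixpoint or at the ``max_iter``/``max_agg``
    bounds, in which case the returned network is flagged truncated.
    """
    net = ReactionNetwork(parameters=dict(model.parameters))
    index_of: dict[str, int] = {}

    def add_species(pattern: SpeciesPattern, canon: str,
                    initial: str = "0") -> int:
        if canon in index_of:
            return index_of[canon]
        idx = len(net.species) + 1
        from .parser import parse_species_pattern
        net.species.append(NetSpecies(
            idx, parse_species_pattern(canon), canon, initial))
        index_of[canon] = idx
        return idx

    for pat, amount in model.seed_species:
        if not is_concrete(pat, model.molecule_types):
            raise BnglError(Diagnostic(
                "error", f"seed species {pattern_to_str(pat)} is not "
                "concrete"))
        for comp_sp in ([pat] if pat.is_connected()
                        else _split_components(pat)):
            canon = canonical_form(comp_sp)
            if canon in index_of:
                prev = net.species[index_of[canon] - 1]
                prev.initial_expr = f"({prev.initial_expr})+({amount})"
            else:
                add_species(comp_sp, canon, amount)

    apps = []
    for rule in model.rules:
        apps.append(_RuleApplicator(rule, "forward", model))
        if rule.reversible:
            apps.append(_RuleApplicator(rule, "reverse", model))

    reactions: dict[tuple, list] = {}   # key -> [multiplicity, Reaction stub]
    embed_cache: dict[tuple, list] = {}
    # per (app, pattern): species indices with >=1 embedding
    matchers: list[list[list[int]]] = [
        [[] for _ in app.patterns] for app in apps]
    scanned = 0   # species indices <= scanned have been matched

    def scan_new_species(n_before):
        nonlocal scanned
        for sp_idx in range(scanned + 1, n_before + 1):
            pat_obj = net.species[sp_idx - 1].pattern
            for app_i, app in enumerate(apps):
                for pat_i, pat in enumerate(app.patterns):
                    es = embed(pat, pat_obj)
                    if es:
                        embed_cache[(app_i, pat_i, sp_idx)] = es
                        matchers[app_i][pat_i].append(sp_idx)
        scanned = n_before

    new_since = 1    # species with index >= new_since are unprocessed
    rounds = 0
    while rounds < max_iter:
        n_before = len(net.species)
        if new_since > n_before:
            break    # fixpoint: nothing new to process
        frontier_start = new_since
        scan_new_species(n_before)
        for app_i, app in enumerate(apps):
            k = len(app.patterns)
            if k == 0:
                _record_synthesis(app, reactions, add_species, max_agg, net)
                continue
            for tup in itertools.product(*matchers[app_i]):
                if not any(t >= frontier_start for t in tup):
                    continue
                per_pat = [embed_cache[(app_i, pi, sp_idx)]
                           for pi, sp_idx in enumerate(tup)]
                for combo in itertools.product(*per_pat):
                    _record_application(app, tup, combo, reactions,
                                        add_species, max_agg, net)
        new_since = n_before + 1
        rounds += 1
    if new_since <= len(net.species):
        net.truncated = True
        net.truncation_reason = net.truncation_reason or "max_iter"

    net.reactions = [stub for _m, stub in reactions.values()]
    for i, rxn in enumerate(net.reactions, start=1):
        rxn.index = i
    net.observable_groups = evaluate_observables(net, model)
    return net


def _record_synthesis(app, reactions, add_species, max_agg, net):
    products = []
    out = apply_rule_instance(app, [], [])
    for sp in out:
        if len(sp.molecules) > max_agg:
            net.truncated = True
            net.truncation_reason = net.truncation_reason or "max_agg"
            return
        products.append(add_species(sp, canonical_form(sp)))
    key = ((), tuple(sorted(products)), app.rdir)
    if key not in reactions:
        reactions[key] = [1, Reaction(0, (), tuple(sorted(products)),
                                      app.rate_expr, 1.0 / app.g, app.rdir)]


def _record_application(app, tup, combo, reactions, add_species, max_agg,
                        net):
    species_tuple = [net.species[idx - 1].pattern for idx in tup]
    out = apply_rule_instance(app, species_tuple, list(combo))
    products = []
    for sp in out:
        if len(sp.molecules) > max_agg:
            net.truncated = True
            net.truncation_reason = net.truncation_reason or "max_agg"
            return
        products.append(add_species(sp, canonical_form(sp)))
    key = (tuple(sorted(tup)), tuple(sorted(products)), app.rdir)
    if key in reactions:
        reactions[key][0] += 1
        m = reactions[key][0]
        reactions[key][1].factor = m / app.g
    else:
        reactions[key] = [1, Reaction(0, tuple(sorted(tup)),
                                      tuple(sorted(products)),
                                      app.rate_expr, 1.0 / app.g, app.rdir)]


# ---------------------------------------------------------------------------


def evaluate_observables(net: ReactionNetwork, model: Model
                         ) -> dict[str, list[tuple[int, float]]]:
    """Weighted species groups for each observable.

    ``Molecules`` weights by embedding count (a dimer matching ``A()``
    counts twice); ``Species`` marks matching species with weight 1.
    """
    groups: dict[str, list[tuple[int, float]]] = {}
    for obs in model.observables:
        if obs.kind not in ("Molecules", "Species"):
            raise BnglError(Diagnostic(
                "error", f"unknown observable kind {obs.kind!r}", obs.line))
        entries = []
        for sp in net.species:
            w = 0.0
            for pat in obs.patterns:
                n = len(embed(pat, sp.pattern))
                if obs.kind == "Molecules":
                    w += n
                elif n > 0:
                    w = 1.0
                    break
            if w:
                entries.append((sp.index, float(w)))
        groups[obs.name] = entries
    return groups


def build_species_graph(species: SpeciesPattern):
    """Species graph: one node per molecule *instance*, bond edges between
    component sub-nodes (contact-map style, but not collapsed per type)."""
    import networkx as nx
    g = nx.Graph()
    for mi, mol in enumerate(species.molecules):
        g.add_node(f"m{mi}", kind="molecule", label=mol.name)
        for ci, comp in enumerate(mol.components):
            nid = f"m{mi}/c{ci}"
            g.add_node(nid, kind="component", label=comp.name,
                       owner=f"m{mi}", state=comp.state or "")
            g.add_edge(f"m{mi}", nid, kind="part_of")
    for ends in species.bonds().values():
        if len(ends) == 2:
            (a, ca), (b, cb) = ends
            g.add_edge(f"m{a}/c{ca}", f"m{b}/c{cb}", kind="bond")
    return g
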