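"""Site-graph pattern semantics.

This module implements the primitives everything else is built on:

* :func:`embed` — structure-preserving maps of a pattern into a concrete
  species or another pattern (constraint entailment), collapsed over
  pattern automorphisms;
* :func:`compute_delta` — the reaction center (elements a rule changes)
  and reaction context (elements it requires unchanged) of a rule
  direction, plus the reactant->product molecule correspondence;
* :func:`classify_rule` — bond / state-change / molecular / mixed;
* :func:`canonical_form` — canonical text label of a concrete species,
  identical for isomorphic presentations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

from .model import (
    BnglError, BOUND_ANY, Diagnostic, FREE, RxnRule, SpeciesPattern, WILD,
)
from .serializer import pattern_to_str

Slot = tuple[int, int]          # (molecule index, component index)


# ---------------------------------------------------------------------------
# Embedding


@dataclass
class Embedding:
    """A map from pattern molecules/components into a target."""

    mol_map: tuple[int, ...]                 # pattern mol i -> target mol
    comp_map: dict[Slot, Slot]

    def image_slots(self) -> frozenset[Slot]:
        return frozenset(self.comp_map.values())


def _bond_entails(pbond, tbond, exact: bool) -> bool:
    """Can a target slot with bond ``tbond`` satisfy pattern bond ``pbond``?

    Labeled-bond pairing is checked separately; here only the local kind.
    """
    if exact:
        kind = lambda b: "lab" if isinstance(b, int) else b
        return kind(pbond) == kind(tbond)
    if pbond == WILD:
        return True
    if pbond == FREE:
        return tbond == FREE
    if pbond == BOUND_ANY:
        return isinstance(tbond, int) or tbond == BOUND_ANY
    # labeled: target must carry a labeled bond too
    return isinstance(tbond, int)


def _state_entails(pstate, tstate, exact: bool) -> bool:
    if exact:
        return pstate == tstate
    return pstate is None or pstate == tstate


def embed(pattern: SpeciesPattern, target: SpeciesPattern,
          exact: bool = False, collapse: bool = True) -> list[Embedding]:
    """All embeddings of ``pattern`` into ``target``.

    With ``exact=False`` (the default) constraints are *entailed*: every
    requirement of the pattern is guaranteed by the target — this is both
    concrete-species matching and the pattern-onto-pattern matching used
    by the influence computation.  With ``exact=True`` constraints must be
    equal (used to find automorphisms).  Embeddings that differ only by an
    automorphism of the pattern are collapsed to one representative.
    """
    results: list[Embedding] = []
    n = len(pattern.molecules)
    if n == 0:
        return results
    t_partner = target.bond_partner()
    p_partner = pattern.bond_partner()

    def comp_assignments(pmol, tmol):
        """Injective component maps pattern-mol -> target-mol (by name)."""
        if exact and len(pmol.components) != len(tmol.components):
            return []
        maps: list[dict[int, int]] = [{}]
        for ci, comp in enumerate(pmol.components):
            new_maps = []
            for partial in maps:
                used = set(partial.values())
                for tj, tcomp in enumerate(tmol.components):
                    if tj in used or tcomp.name != comp.name:
                        continue
                    if not _state_entails(comp.state, tcomp.state, exact):
                        continue
                    if not _bond_entails(comp.bond, tcomp.bond, exact):
                        continue
                    new_maps.append({**partial, ci: tj})
            maps = new_maps
            if not maps:
                return []
        return maps

    def backtrack(pi: int, mol_map: list[int], comp_map: dict[Slot, Slot]):
        if pi == n:
            if _bonds_ok(comp_map):
                results.append(Embedding(tuple(mol_map), dict(comp_map)))
            return
        pmol = pattern.molecules[pi]
        for ti, tmol in enumerate(target.molecules):
            if ti in mol_map or tmol.name != pmol.name:
                continue
            for cmap in comp_assignments(pmol, tmol):
                mol_map.append(ti)
                for ci, tj in cmap.items():
                    comp_map[(pi, ci)] = (ti, tj)
                backtrack(pi + 1, mol_map, comp_map)
                for ci in cmap:
                    del comp_map[(pi, ci)]
                mol_map.pop()

    def _bonds_ok(comp_map: dict[Slot, Slot]) -> bool:
        for a, b in p_partner.items():
            ia, ib = comp_map[a], comp_map[b]
            if t_partner.get(ia) != ib:
                return False
            if exact and t_partner.get(ib) != ia:
                return False
        if exact:
            # exact mode: target labeled bonds inside the image must also be
            # paired in the pattern (true automorphism)
            inv = {v: k for k, v in comp_map.items()}
            for ia, ib in t_partner.items():
                if ia in inv and ib in inv:
                    if p_partner.get(inv[ia]) != inv[ib]:
                        return False
        return True

    backtrack(0, [], {})
    if not collapse or len(results) <= 1:
        return results
    return _collapse_automorphic(pattern, results)


def _collapse_automorphic(pattern: SpeciesPattern,
                          embeddings: list[Embedding]) -> list[Embedding]:
    autos = embed(pattern, pattern, exact=True, collapse=False)
    if len(autos) <= 1:
        return embeddings
    seen: set = set()
    out = []
    for e in embeddings:
        orbit_keys = []
        for a in autos:
            mol = tuple(e.mol_map[a.mol_map[i]]
                        for i in range(len(e.mol_map)))
            comp = tuple(sorted((slot, e.comp_map[a.comp_map[slot]])
                                for slot in a.comp_map))
            orbit_keys.append((mol, comp))
        key = min(orbit_keys)
        if key not in seen:
            seen.add(key)
            out.append(e)
    return out


def count_embeddings(pattern: SpeciesPattern, target: SpeciesPattern) -> int:
    return len(embed(pattern, target))


# ---------------------------------------------------------------------------
# Reaction center / context


@dataclass
class RuleDelta:
    """Center and context of one rule direction.

    Elements are tagged tuples over flat molecule indices of the direction's
    reactant side (and product side for created material):

    center:  ``("bond+", slotA, slotB)``, ``("bond-", slotA, slotB)``,
             ``("state", slot, from, to)``, ``("mol+", prod_idx)``,
             ``("mol-", reac_idx)``
    context: ``("mol", reac_idx)``, ``("free", slot)``, ``("bound", slot)``,
             ``("bond=", slotA, slotB)``, ``("state=", slot, state)``

    Slots are ``(flat molecule index, component index)``; slots on created
    molecules are tagged ``("new", prod_idx, comp_idx)``.
    """

    rule_label: str
    direction: str
    center: set = field(default_factory=set)
    context: set = field(default_factory=set)
    molecule_map: dict[int, int] = field(default_factory=dict)
    comp_map: dict[Slot, Slot] = field(default_factory=dict)
    created: list[int] = field(default_factory=list)
    deleted: list[int] = field(default_factory=list)
    warnings: list[Diagnostic] = field(default_factory=list)
    # flat molecule tables: (pattern index, molecule index within pattern)
    reactant_mols: list[tuple[int, int]] = field(default_factory=list)
    product_mols: list[tuple[int, int]] = field(default_factory=list)

    def center_kinds(self) -> set[str]:
        kinds = set()
        for el in self.center:
            if el[0] in ("bond+", "bond-"):
                kinds.add("bond")
            elif el[0] == "state":
                kinds.add("state")
            else:
                kinds.add("mol")
        return kinds

    def center_slots(self, side: str = "reactant") -> set[Slot]:
        """Flat component slots that carry center elements on one side.

        For ``side="reactant"`` these are the slots whose constraints a
        firing consumes (deleted-bond ends, created-bond ends, from-state
        slots); for ``side="product"`` the slots as realized after firing.
        ``compute_delta`` always records reactant-side slots; product-side
        realization is obtained through the molecule/component maps.
        """
        slots: set[Slot] = set()
        for el in self.center:
            if el[0] in ("bond+", "bond-"):
                slots.update(s for s in el[1:] if s[0] != "new")
            elif el[0] == "state":
                slots.add(el[1])
        if side == "reactant":
            return slots
        return {self.comp_map[s] for s in slots if s in self.comp_map}

    def center_mols(self, side: str = "reactant") -> set[int]:
        if side == "reactant":
            return {el[1] for el in self.center if el[0] == "mol-"}
        return {el[1] for el in self.center if el[0] == "mol+"}


def _flat_mols(patterns: list[SpeciesPattern]) -> list[tuple[int, int]]:
    return [(pi, mi) for pi, pat in enumerate(patterns)
            for mi in range(len(pat.molecules))]


def _get_mol(patterns, flat, idx):
    pi, mi = flat[idx]
    return patterns[pi].molecules[mi]


def compute_delta(rule: RxnRule, direction: str = "forward") -> RuleDelta:
    """Element-wise difference between a rule direction's two sides."""
    reactants, products = rule.sides(direction)
    delta = RuleDelta(rule.label, direction)
    delta.reactant_mols = _flat_mols(reactants)
    delta.product_mols = _flat_mols(products)

    # group flat indices by molecule name, in order of occurrence
    def by_name(flat, patterns):
        groups: dict[str, list[int]] = {}
        for idx, (pi, mi) in enumerate(flat):
            groups.setdefault(patterns[pi].molecules[mi].name, []).append(idx)
        return groups

    r_groups = by_name(delta.reactant_mols, reactants)
    p_groups = by_name(delta.product_mols, products)

    # candidate molecule maps: per name, injections of the shorter list into
    # the longer; positional map first, alternatives for ambiguity resolution
    names = sorted(set(r_groups) | set(p_groups))
    per_name_options: list[list[list[tuple[int, int]]]] = []
    ambiguous = False
    for name in names:
        r_idx = r_groups.get(name, [])
        p_idx = p_groups.get(name, [])
        k = min(len(r_idx), len(p_idx))
        options = []
        if k == 0:
            options.append([])
        elif len(r_idx) <= len(p_idx):
            perms = itertools.permutations(p_idx, k)
            options = [list(zip(r_idx, perm)) for perm in perms]
        else:
            perms = itertools.permutations(r_idx, k)
            options = [[(ri, pj) for ri, pj in zip(perm, p_idx)]
                       for perm in perms]
        if len(options) > 24:
            options = options[:24]
        if len(options) > 1:
            ambiguous = True
        per_name_options.append(options)

    best = None
    best_center = None
    n_best = 0
    map_error: Optional[BnglError] = None
    for combo in itertools.product(*per_name_options):
        mol_map = dict(pair for opt in combo for pair in opt)
        try:
            center, context, comp_map, warns = _diff(
                rule, direction, reactants, products,
                delta.reactant_mols, delta.product_mols, mol_map)
        except BnglError as e:
            map_error = map_error or e   # invalid under this map only
            continue
        if center is None:
            continue
        key = len(center)
        if best is None or key < best:
            best, best_center = key, (mol_map, center, context, comp_map,
                                      warns)
            n_best = 1
        elif key == best and frozenset(center) != frozenset(best_center[1]):
            n_best += 1
    if best_center is None:
        if map_error is not None:
            raise map_error
        raise BnglError(Diagnostic(
            "error", f"cannot map reactant to product molecules in rule "
            f"{rule.label} ({direction})", rule.line))
    mol_map, center, context, comp_map, warns = best_center
    delta.molecule_map = mol_map
    delta.center = center
    delta.context = context
    delta.comp_map = comp_map
    delta.warnings = warns
    if ambiguous and n_best > 1:
        delta.warnings.append(Diagnostic(
            "warning", f"ambiguous molecule correspondence in rule "
            f"{rule.label} ({direction}); minimal-change map chosen by "
            "position", rule.line))
    delta.deleted = [i for i in range(len(delta.reactant_mols))
                     if i not in mol_map]
    delta.created = [j for j in range(len(delta.product_mols))
                     if j not in set(mol_map.values())]
    for i in delta.deleted:
        delta.center.add(("mol-", i))
    for j in delta.created:
        delta.center.add(("mol+", j))
        # created molecules must be fully concrete at application time;
        # their bonds are handled in _diff via "new" slots
    for i in range(len(delta.reactant_mols)):
        if i not in delta.deleted:
            delta.context.add(("mol", i))
    return delta


def _diff(rule, direction, reactants, products, r_flat, p_flat, mol_map):
    """Center/context for a fixed molecule map; None center on hard conflict."""
    warns: list[Diagnostic] = []
    center: set = set()
    context: set = set()
    comp_map: dict[Slot, Slot] = {}

    # flat-slot bond partners on each side
    def partners(patterns, flat):
        out: dict[Slot, Slot] = {}
        offset: dict[tuple[int, int], int] = {pm: i
                                              for i, pm in enumerate(flat)}
        for pi, pat in enumerate(patterns):
            for ends in pat.bonds().values():
                if len(ends) != 2:
                    return None
                (a_m, a_c), (b_m, b_c) = ends
                fa = (offset[(pi, a_m)], a_c)
                fb = (offset[(pi, b_m)], b_c)
                out[fa] = fb
                out[fb] = fa
        return out

    r_partner = partners(reactants, r_flat)
    p_partner = partners(products, p_flat)
    if r_partner is None or p_partner is None:
        return None, None, None, warns
    inv_map = {v: k for k, v in mol_map.items()}

    # component correspondence per mapped molecule (by name, positional)
    for ri, pj in mol_map.items():
        rmol = _get_mol(reactants, r_flat, ri)
        pmol = _get_mol(products, p_flat, pj)
        r_occ: dict[str, list[int]] = {}
        for ci, c in enumerate(rmol.components):
            r_occ.setdefault(c.name, []).append(ci)
        p_occ: dict[str, list[int]] = {}
        for cj, c in enumerate(pmol.components):
            p_occ.setdefault(c.name, []).append(cj)
        for name_, r_list in r_occ.items():
            p_list = p_occ.get(name_, [])
            for ci, cj in zip(r_list, p_list):
                comp_map[(ri, ci)] = (pj, cj)
            if len(r_list) > len(p_list):
                warns.append(Diagnostic(
                    "warning", f"component {name_} of {rmol.name} not "
                    f"mentioned on product side of rule {rule.label}; "
                    "treated as unchanged", rule.line))

    # product-side slot -> reactant-side slot (or ("new", ...))
    inv_comp = {v: k for k, v in comp_map.items()}

    def pslot_ref(pslot: Slot):
        if pslot in inv_comp:
            return inv_comp[pslot]
        return ("new", pslot[0], pslot[1])

    # walk reactant slots: compare with mapped product slot
    for ri in range(len(r_flat)):
        rmol = _get_mol(reactants, r_flat, ri)
        for ci, rcomp in enumerate(rmol.components):
            rslot = (ri, ci)
            pslot = comp_map.get(rslot)
            pcomp = None
            if pslot is not None:
                pcomp = _get_mol(products, p_flat, pslot[0]).components[pslot[1]]
            # --- state ---
            if pcomp is not None:
                if rcomp.state == pcomp.state:
                    if rcomp.state is not None:
                        context.add(("state=", rslot, rcomp.state))
                elif pcomp.state is None:
                    warns.append(Diagnostic(
                        "warning", f"state of {rmol.name}.{rcomp.name} "
                        f"dropped on product side of rule {rule.label}; "
                        "treated as unchanged", rule.line))
                    context.add(("state=", rslot, rcomp.state))
                else:
                    center.add(("state", rslot, rcomp.state, pcomp.state))
            elif rcomp.state is not None:
                context.add(("state=", rslot, rcomp.state))
            # --- bond ---
            rb = rcomp.bond
            pb = pcomp.bond if pcomp is not None else None
            if isinstance(rb, int):
                partner_r = r_partner.get(rslot)
                partner_p = p_partner.get(pslot) if pslot is not None else None
                if pcomp is None:
                    context.add(_bond_el("bond=", rslot, partner_r))
                elif isinstance(pb, int):
                    # bond on both sides: same partner (via map) = unchanged
                    if partner_p is not None and \
                            pslot_ref(partner_p) == partner_r:
                        context.add(_bond_el("bond=", rslot, partner_r))
                    else:
                        center.add(_bond_el("bond-", rslot, partner_r))
                        center.add(_bond_el(
                            "bond+", rslot,
                            pslot_ref(partner_p) if partner_p else None))
                elif pb == FREE:
                    center.add(_bond_el("bond-", rslot, partner_r))
                elif pb == BOUND_ANY:
                    context.add(("bound", rslot))
                else:  # WILD on product
                    context.add(_bond_el("bond=", rslot, partner_r))
            elif rb == FREE:
                if pcomp is not None and isinstance(pb, int):
                    partner_p = p_partner.get(pslot)
                    center.add(_bond_el(
                        "bond+", rslot,
                        pslot_ref(partner_p) if partner_p else None))
                else:
                    context.add(("free", rslot))
            elif rb == BOUND_ANY:
                if pcomp is not None and isinstance(pb, int):
                    raise BnglError(Diagnostic(
                        "error", f"'!+' reactant bond becomes a labeled bond "
                        f"in rule {rule.label}: created bond partner is "
                        "undetermined", rule.line))
                context.add(("bound", rslot))
            # WILD: no constraint, never center or context

    # created bonds between two created molecules (no reactant-side slot)
    for pslot, qslot in p_partner.items():
        if pslot in inv_comp or qslot in inv_comp:
            continue
        if pslot < qslot:
            center.add(("bond+", ("new", pslot[0], pslot[1]),
                        ("new", qslot[0], qslot[1])))

    # dedupe symmetric bond elements (each bond recorded from both ends)
    return center, context, comp_map, warns


def _bond_el(tag: str, slot_a, slot_b):
    # normalize end ordering so the same bond from either end is one element
    if slot_b is None:
        return (tag, slot_a, None)
    a, b = sorted([slot_a, slot_b], key=_slot_key)
    return (tag, a, b)


def _slot_key(s):
    if isinstance(s, tuple) and len(s) == 3 and s[0] == "new":
        return (1, s[1], s[2])
    return (0, s[0], s[1])


# ---------------------------------------------------------------------------
# Rule classification


def classify_rule(rule: RxnRule, direction: str = "forward",
                  delta: Optional[RuleDelta] = None) -> str:
    """Category of a rule direction by what its center changes.

    ``bond_rule`` (only bonds), ``state_change_rule`` (only states),
    ``molecular_rule`` (only molecule creation/deletion), ``mixed``
    (several kinds), ``null_rule`` (empty center).
    """
    delta = delta or compute_delta(rule, direction)
    kinds = delta.center_kinds()
    if not kinds:
        return "null_rule"
    if kinds == {"bond"}:
        return "bond_rule"
    if kinds == {"state"}:
        return "state_change_rule"
    if kinds == {"mol"}:
        return "molecular_rule"
    return "mixed"


# ---------------------------------------------------------------------------
# Canonical labeling of concrete species


def is_concrete(pattern: SpeciesPattern, molecule_types=None) -> bool:
    """Concrete: every bond is labeled or free, no wildcards or '!+'."""
    for _mi, _ci, comp in pattern.slots():
        if comp.bond in (WILD, BOUND_ANY):
            return False
    if molecule_types:
        types = {mt.name: mt for mt in molecule_types}
        for mol in pattern.molecules:
            mt = types.get(mol.name)
            if mt is None or len(mol.components) != len(mt.components):
                return False
            declared_states = {}
            for cname, states in mt.components:
                declared_states.setdefault(cname, []).append(states)
            for comp in mol.components:
                if comp.state is None:
                    anystates = [s for ss in
                                 declared_states.get(comp.name, [[]])
                                 for s in ss]
                    if anystates:
                        return False
    return True


def canonical_form(species: SpeciesPattern) -> str:
    """Canonical text label; identical for isomorphic concrete species.

    Iterative neighborhood refinement over molecule colors with
    individualization on ties, emitting the lexicographically minimal
    rendering.  Exact at the scale this package targets (validated against
    an exhaustive permutation oracle in the test-suite).
    """
    if not species.is_connected():
        raise BnglError(Diagnostic(
            "error", "canonical_form requires a connected species: "
            + pattern_to_str(species)))
    n = len(species.molecules)
    if n == 0:
        return ""
    partner = species.bond_partner()

    def initial_color(mi):
        mol = species.molecules[mi]
        sig = tuple(sorted(
            (c.name, c.state or "", "b" if isinstance(c.bond, int) else "f")
            for c in mol.components))
        return (mol.name, sig)

    init_keys = sorted({initial_color(mi) for mi in range(n)})
    init_rank = {k: i for i, k in enumerate(init_keys)}
    colors0 = {mi: init_rank[initial_color(mi)] for mi in range(n)}

    def refine(colors: dict[int, int]) -> dict[int, int]:
        while True:
            sigs = {}
            for mi in range(n):
                nbrs = []
                for ci, comp in enumerate(species.molecules[mi].components):
                    p = partner.get((mi, ci))
                    if p is not None:
                        nbrs.append((comp.name,
                                     species.molecules[p[0]]
                                     .components[p[1]].name,
                                     colors[p[0]]))
                sigs[mi] = (colors[mi], tuple(sorted(nbrs)))
            ranks = {s: i for i, s in enumerate(sorted(set(sigs.values())))}
            new = {mi: ranks[sigs[mi]] for mi in range(n)}
            if len(set(new.values())) == len(set(colors.values())):
                return new
            colors = new

    best: list[Optional[str]] = [None]

    def search(colors):
        colors = refine(colors)
        classes: dict[int, list[int]] = {}
        for mi, c in colors.items():
            classes.setdefault(c, []).append(mi)
        tied = [mols for mols in classes.values() if len(mols) > 1]
        if not tied:
            order = [mi for _c, mi in
                     sorted((c, mi) for mi, c in colors.items())]
            s = _render(species, order, partner)
            if best[0] is None or s < best[0]:
                best[0] = s
            return
        # individualize within the smallest, lowest-color tied class
        target = min(tied, key=lambda mols: (len(mols),
                                             min(colors[m] for m in mols)))
        for mi in target:
            branched = {mj: c * 2 for mj, c in colors.items()}
            branched[mi] = colors[mi] * 2 + 1
            search(branched)

    search(colors0)
    return best[0]


def _render(species: SpeciesPattern, order: list[int], partner) -> str:
    pos = {mi: k for k, mi in enumerate(order)}
    bond_ids: dict[frozenset, int] = {}

    def slot_sort_key(mi, ci):
        comp = species.molecules[mi].components[ci]
        p = partner.get((mi, ci))
        bond_key = (1, 0, "") if p is None else (0, pos[p[0]],
                                                 species.molecules[p[0]]
                                                 .components[p[1]].name)
        return (comp.name, comp.state or "", bond_key)

    parts = []
    counter = itertools.count(1)
    ordered_slots = {}
    for mi in order:
        mol = species.molecules[mi]
        ordered_slots[mi] = sorted(range(len(mol.components)),
                                   key=lambda ci: slot_sort_key(mi, ci))
    # assign bond ids in traversal order
    for mi in order:
        for ci in ordered_slots[mi]:
            p = partner.get((mi, ci))
            if p is not None:
                key = frozenset([(mi, ci), p])
                if key not in bond_ids:
                    bond_ids[key] = next(counter)
    for mi in order:
        mol = species.molecules[mi]
        comps = []
        for ci in ordered_slots[mi]:
            comp = mol.components[ci]
            text = comp.name
            if comp.state is not None:
                text += f"~{comp.state}"
            p = partner.get((mi, ci))
            if p is not None:
                text += f"!{bond_ids[frozenset([(mi, ci), p])]}"
            comps.append(text)
        parts.append(mol.name + "(" + ",".join(comps) + ")")
    return ".".join(parts)
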