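"""Independent brute-force oracles used to validate the implementation.

Everything here is written as direct exhaustive enumeration over
permutations/subsets, deliberately sharing no code with the library's
algorithms, and is only usable at desk scale (a handful of molecules).
"""

from __future__ import annotations

import itertools

from rulemap.model import BOUND_ANY, FREE, SpeciesPattern, WILD


# ---------------------------------------------------------------------------
# Embedding oracle


def _comp_matches(pc, tc, exact: bool) -> bool:
    if pc.name != tc.name:
        return False
    if exact:
        if pc.state != tc.state:
            return False
        pk = "lab" if isinstance(pc.bond, int) else pc.bond
        tk = "lab" if isinstance(tc.bond, int) else tc.bond
        return pk == tk
    if pc.state is not None and pc.state != tc.state:
        return False
    if pc.bond == WILD:
        return True
    if pc.bond == FREE:
        return tc.bond == FREE
    if pc.bond == BOUND_ANY:
        return isinstance(tc.bond, int) or tc.bond == BOUND_ANY
    return isinstance(tc.bond, int)


def _all_maps(pattern: SpeciesPattern, target: SpeciesPattern,
              exact: bool):
    """Every structure-preserving (mol map, comp map) pair, uncollapsed."""
    np_, nt = len(pattern.molecules), len(target.molecules)
    if np_ == 0 or np_ > nt:
        return
    p_partner = pattern.bond_partner()
    t_partner = target.bond_partner()
    for tmols in itertools.permutations(range(nt), np_):
        if any(pattern.molecules[i].name != target.molecules[t].name
               for i, t in enumerate(tmols)):
            continue
        per_mol_maps = []
        dead = False
        for pi, ti in enumerate(tmols):
            pmol, tmol = pattern.molecules[pi], target.molecules[ti]
            if exact and len(pmol.components) != len(tmol.components):
                dead = True
                break
            options = []
            tidx = range(len(tmol.components))
            for assignment in itertools.permutations(
                    tidx, len(pmol.components)):
                if all(_comp_matches(pmol.components[ci],
                                     tmol.components[assignment[ci]], exact)
                       for ci in range(len(pmol.components))):
                    options.append(assignment)
            if not options:
                dead = True
                break
            per_mol_maps.append(options)
        if dead:
            continue
        for combo in itertools.product(*per_mol_maps):
            comp_map = {}
            for pi, assignment in enumerate(combo):
                for ci, tj in enumerate(assignment):
                    comp_map[(pi, ci)] = (tmols[pi], tj)
            ok = True
            for a, b in p_partner.items():
                if t_partner.get(comp_map[a]) != comp_map[b]:
                    ok = False
                    break
            if ok and exact:
                inv = {v: k for k, v in comp_map.items()}
                for ia, ib in t_partner.items():
                    if ia in inv and ib in inv and \
                            p_partner.get(inv[ia]) != inv[ib]:
                        ok = False
                        break
            if ok:
                yield tmols, comp_map


def count_embeddings_oracle(pattern: SpeciesPattern,
                            target: SpeciesPattern) -> int:
    """Embedding count collapsed over pattern automorphisms."""
    maps = list(_all_maps(pattern, target, exact=False))
    autos = list(_all_maps(pattern, pattern, exact=True))
    if not maps:
        return 0
    reps = set()
    for tmols, comp_map in maps:
        orbit = []
        for amols, acomp in autos:
            # compose: pattern -σ-> pattern -f-> target
            mol = tuple(tmols[amols[i]] for i in range(len(tmols)))
            comp = tuple(sorted((slot, comp_map[acomp[slot]])
                                for slot in acomp))
            orbit.append((mol, comp))
        reps.add(min(orbit))
    return len(reps)


# ---------------------------------------------------------------------------
# Isomorphism oracle (concrete species)


def isomorphic_oracle(a: SpeciesPattern, b: SpeciesPattern) -> bool:
    if len(a.molecules) != len(b.molecules):
        return False
    for _ in _all_maps(a, b, exact=True):
        return True
    return len(a.molecules) == 0


# ---------------------------------------------------------------------------
# Rule delta oracle: exhaustive molecule-map diff


def _side_elements(patterns, mol_map_domain=None):
    """Flat molecules, per-slot (state, bond kind), bond partner map."""
    flat = []
    for pi, pat in enumerate(patterns):
        for mi, mol in enumerate(pat.molecules):
            flat.append((pi, mi, mol))
    partner = {}
    for pi, pat in enumerate(patterns):
        base = sum(1 for f in flat if f[0] < pi)
        for label, ends in pat.bonds().items():
            (am, ac), (bm, bc) = ends
            partner[(base + am, ac)] = (base + bm, bc)
            partner[(base + bm, bc)] = (base + am, ac)
    return flat, partner


def delta_oracle(rule, direction: str):
    """(center, context) chosen over all name-preserving molecule maps,
    minimizing |center|; element tags match RuleDelta's scheme."""
    reactants, products = rule.sides(direction)
    r_flat, r_partner = _side_elements(reactants)
    p_flat, p_partner = _side_elements(products)

    r_names = {}
    for i, (_pi, _mi, mol) in enumerate(r_flat):
        r_names.setdefault(mol.name, []).append(i)
    p_names = {}
    for j, (_pi, _mi, mol) in enumerate(p_flat):
        p_names.setdefault(mol.name, []).append(j)

    options_per_name = []
    for name in sorted(set(r_names) | set(p_names)):
        ri, pj = r_names.get(name, []), p_names.get(name, [])
        k = min(len(ri), len(pj))
        opts = []
        if k == 0:
            opts = [[]]
        elif len(ri) <= len(pj):
            opts = [list(zip(ri, perm))
                    for perm in itertools.permutations(pj, k)]
        else:
            opts = [list(zip(perm, pj))
                    for perm in itertools.permutations(ri, k)]
        options_per_name.append(opts)

    best = None
    for combo in itertools.product(*options_per_name):
        mol_map = dict(p for opt in combo for p in opt)
        result = _diff_for_map(rule, reactants, products, r_flat, p_flat,
                               r_partner, p_partner, mol_map)
        if result is None:
            continue
        center, context = result
        if best is None or len(center) < len(best[0]):
            best = (center, context)
    return best


def _diff_for_map(rule, reactants, products, r_flat, p_flat, r_partner,
                  p_partner, mol_map):
    center, context = set(), set()
    comp_map = {}
    for ri, pj in mol_map.items():
        rmol = r_flat[ri][2]
        pmol = p_flat[pj][2]
        seen_r, seen_p = {}, {}
        for ci, c in enumerate(rmol.components):
            seen_r.setdefault(c.name, []).append(ci)
        for cj, c in enumerate(pmol.components):
            seen_p.setdefault(c.name, []).append(cj)
        for name, r_list in seen_r.items():
            for ci, cj in zip(r_list, seen_p.get(name, [])):
                comp_map[(ri, ci)] = (pj, cj)
    inv_comp = {v: k for k, v in comp_map.items()}

    def pref(pslot):
        return inv_comp.get(pslot, ("new", pslot[0], pslot[1]))

    def bond_el(tag, a, b):
        def key(s):
            return (1, s[1], s[2]) if s[0] == "new" else (0, s[0], s[1])
        if b is None:
            return (tag, a, None)
        x, y = sorted([a, b], key=key)
        return (tag, x, y)

    for ri in range(len(r_flat)):
        rmol = r_flat[ri][2]
        if ri not in mol_map:
            center.add(("mol-", ri))
            continue
        context.add(("mol", ri))
        for ci, rc in enumerate(rmol.components):
            rslot = (ri, ci)
            pslot = comp_map.get(rslot)
            pc = p_flat[pslot[0]][2].components[pslot[1]] if pslot else None
            # states
            if pc is not None and rc.state != pc.state and \
                    pc.state is not None:
                center.add(("state", rslot, rc.state, pc.state))
            elif rc.state is not None:
                context.add(("state=", rslot, rc.state))
            # bonds
            if isinstance(rc.bond, int):
                rp = r_partner[rslot]
                if pc is None or not isinstance(pc.bond, int):
                    if pc is not None and pc.bond == FREE:
                        center.add(bond_el("bond-", rslot, rp))
                    elif pc is not None and pc.bond == BOUND_ANY:
                        context.add(("bound", rslot))
                    else:
                        context.add(bond_el("bond=", rslot, rp))
                else:
                    pp = p_partner.get(pslot)
                    if pp is not None and pref(pp) == rp:
                        context.add(bond_el("bond=", rslot, rp))
                    else:
                        center.add(bond_el("bond-", rslot, rp))
                        center.add(bond_el("bond+", rslot,
                                           pref(pp) if pp else None))
            elif rc.bond == FREE:
                if pc is not None and isinstance(pc.bond, int):
                    pp = p_partner.get(pslot)
                    center.add(bond_el("bond+", rslot,
                                       pref(pp) if pp else None))
                else:
                    context.add(("free", rslot))
            elif rc.bond == BOUND_ANY:
                if pc is not None and isinstance(pc.bond, int):
                    return None       # undetermined partner: hard error
                context.add(("bound", rslot))
    mapped_p = set(mol_map.values())
    for pj in range(len(p_flat)):
        if pj not in mapped_p:
            center.add(("mol+", pj))
    for pslot, qslot in p_partner.items():
        if pslot in inv_comp or qslot in inv_comp:
            continue
        if pslot < qslot:
            center.add(("bond+", ("new", pslot[0], pslot[1]),
                        ("new", qslot[0], qslot[1])))
    return center, context


# ---------------------------------------------------------------------------
# Influence relation oracle: exhaustive overlap enumeration


def _bond_conflict(a, b) -> bool:
    if a == WILD or b == WILD:
        return False
    ab = a == BOUND_ANY or isinstance(a, int)
    bb = b == BOUND_ANY or isinstance(b, int)
    return ab != bb


def pattern_relation_oracle(p2: SpeciesPattern, p1: SpeciesPattern,
                            center_slots: set, center_mols: set) -> str:
    """full / partial / none by enumerating every map and every overlap."""
    if not center_slots and not center_mols:
        return "none"
    # full: total entailment map touching center (reuse exhaustive maps)
    for tmols, comp_map in _all_maps(p2, p1, exact=False):
        touched = (set(comp_map.values()) & center_slots
                   or set(tmols) & center_mols)
        if touched:
            return "full"
    # partial: enumerate all partial molecule maps and component submaps
    n2, n1 = len(p2.molecules), len(p1.molecules)
    for size in range(1, n2 + 1):
        for mols2 in itertools.combinations(range(n2), size):
            for mols1 in itertools.permutations(range(n1), size):
                if any(p2.molecules[a].name != p1.molecules[b].name
                       for a, b in zip(mols2, mols1)):
                    continue
                if _consistent_overlap_touches(p2, p1, mols2, mols1,
                                               center_slots, center_mols):
                    return "partial"
    return "none"


def _consistent_overlap_touches(p2, p1, mols2, mols1, center_slots,
                                center_mols) -> bool:
    if set(mols1) & center_mols:
        return True
    # try every consistent component pairing; look for center touch
    for a, b in zip(mols2, mols1):
        m2, m1 = p2.molecules[a], p1.molecules[b]
        for ci, c2 in enumerate(m2.components):
            for cj, c1 in enumerate(m1.components):
                if c1.name != c2.name:
                    continue
                if (b, cj) not in center_slots:
                    continue
                if c2.state is not None and c1.state is not None \
                        and c2.state != c1.state:
                    continue
                if _bond_conflict(c2.bond, c1.bond):
                    continue
                return True
    return False
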