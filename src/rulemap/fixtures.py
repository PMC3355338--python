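"""Deterministic model fixtures and a random-model generator.

The bundled fixtures emulate the classic teaching and debugging models of
rule-based signaling: the reduced Lyn-binding model (receptor Rec, kinase
Lyn, bivalent ligand Lig) in its correct and incorrect formulations, a
symmetric dimerization model, a first-order decay model, a two-group model
whose rules split into molecule-disjoint subsets, and a reconstruction of
the published early-EGFR network model.  ``random_model`` produces
well-formed models from a seed for property tests.
"""

from __future__ import annotations

import importlib.resources
import random
from dataclasses import dataclass, field

from .model import Model
from .parser import parse_model
from .serializer import serialize_model


def _parse(name: str, text: str) -> Model:
    return parse_model(text, name=name)


def lyn_fixture(correct: bool = True) -> Model:
    """Reduced Lyn-binding model: Lig(l,l), Rec(a,b), Lyn(U,SH2).

    The two Lyn rules bind Lyn to the receptor b subunit through either
    its SH2 or its unique (U) domain; the correct formulation requires
    the *other* Lyn site to be free, which prevents one Lyn from bridging
    two receptors.  The incorrect formulation drops that context and
    admits unbounded chains.  The ligand/receptor rules (binding and
    crosslinking) are a reconstruction of the unprinted remainder of the
    reduced model; all rate constants are arbitrary unit values.
    """
    if correct:
        lyn_rules = """\
  LynSH2: Rec(b) + Lyn(SH2,U) <-> Rec(b!1).Lyn(SH2!1,U) kpL1, kmL1
  LynU: Rec(b) + Lyn(U,SH2) <-> Rec(b!1).Lyn(SH2,U!1) kpL2, kmL2"""
    else:
        lyn_rules = """\
  LynSH2: Rec(b) + Lyn(SH2) <-> Rec(b!1).Lyn(SH2!1) kpL1, kmL1
  LynU: Rec(b) + Lyn(U) <-> Rec(b!1).Lyn(U!1) kpL2, kmL2"""
    text = f"""\
begin parameters
  kp1 1
  km1 1
  kp2 1
  km2 1
  kpL1 1
  kmL1 1
  kpL2 1
  kmL2 1
end parameters
begin molecule types
  Lig(l,l)
  Rec(a,b)
  Lyn(U,SH2)
end molecule types
begin seed species
  Lig(l,l) 100
  Rec(a,b) 100
  Lyn(U,SH2) 50
end seed species
begin observables
  Molecules RecBound Rec(a!+)
  Molecules LynBound Lyn(SH2!+) Lyn(U!+)
end observables
begin reaction rules
  LR: Lig(l,l) + Rec(a) <-> Lig(l!1,l).Rec(a!1) kp1, km1
  LRR: Lig(l,l!+) + Rec(a) <-> Lig(l!1,l!+).Rec(a!1) kp2, km2
{lyn_rules}
end reaction rules
"""
    return _parse("lyn_correct" if correct else "lyn_incorrect", text)


def dimer_fixture() -> Model:
    """Symmetric dimerization: one molecule type, 2 species, 2 reactions."""
    return _parse("dimer", """\
begin parameters
  kf 0.01
  kr 2.0
end parameters
begin molecule types
  A(a)
end molecule types
begin seed species
  A(a) 500
end seed species
begin observables
  Molecules Amono A(a)
  Species Adimer A(a!1).A(a!1)
  Molecules Atotal A()
end observables
begin reaction rules
  dim: A(a) + A(a) <-> A(a!1).A(a!1) kf, kr
end reaction rules
""")


def decay_fixture(k: float = 0.7, a0: float = 1000.0) -> Model:
    """First-order decay A -> 0; the ODE solution is A0*exp(-k*t)."""
    return _parse("decay", f"""\
begin parameters
  k {k}
  A0 {a0}
end parameters
begin molecule types
  A()
end molecule types
begin seed species
  A() A0
end seed species
begin observables
  Molecules Atotal A()
end observables
begin reaction rules
  deg: A() -> 0 k
end reaction rules
""")


def two_group_fixture() -> Model:
    """Rules over two molecule-disjoint groups: the influence graph has
    two weakly connected components (a completeness warning sign)."""
    return _parse("two_group", """\
begin parameters
  k1 1
  k2 1
  k3 1
  k4 1
end parameters
begin molecule types
  A(x)
  B(y)
  C(s~off~on)
  D(z)
end molecule types
begin seed species
  A(x) 10
  B(y) 10
  C(s~off) 10
  D(z) 10
end seed species
begin observables
  Molecules AB A(x!1).B(y!1)
  Molecules Con C(s~on)
end observables
begin reaction rules
  bindAB: A(x) + B(y) <-> A(x!1).B(y!1) k1, k2
  flipC: C(s~off) -> C(s~on) k3
  flipCback: C(s~on) -> C(s~off) k4
end reaction rules
""")


def egfr_fixture() -> Model:
    """Reconstruction of the published early-EGFR signaling model
    (EGF, EGFR, Grb2, Shc, Sos; 23 reversible/irreversible rules).

    Synthetic reconstruction from the published reaction scheme, bundled
    as ``data/egfr_net_reconstructed.bngl``; generating its network yields
    356 species connected by 3749 unidirectional reactions.
    """
    text = (importlib.resources.files("rulemap") / "data"
            / "egfr_net_reconstructed.bngl").read_text()
    return parse_model(text, name="egfr_net_reconstructed")


# ---------------------------------------------------------------------------
# Random model generation


@dataclass
class FixtureSpec:
    """Parameters of the random model generator (pure function of seed)."""

    seed: int = 0
    n_molecule_types: int = 3
    sites_per_molecule: tuple[int, int] = (1, 3)
    states_per_site: tuple[int, int] = (0, 2)
    n_rules: int = 4
    # weights over (bond, state_change, molecular) rules
    rule_mix: tuple[float, float, float] = (0.6, 0.3, 0.1)
    reversible_p: float = 0.5
    compartment_depth: int = 0
    duplicate_site_p: float = 0.15

    def __post_init__(self):
        if any(c < 0 for c in (self.n_molecule_types, self.n_rules)):
            raise ValueError("counts must be non-negative")
        if abs(sum(self.rule_mix) - 1.0) > 1e-9:
            raise ValueError("rule_mix weights must sum to 1")


_STATE_NAMES = ["U", "P", "X", "Y"]


def random_model(spec: FixtureSpec) -> Model:
    """Seed-deterministic, always-valid random model."""
    rng = random.Random(spec.seed)
    lines = ["begin parameters"]
    n_params = max(spec.n_rules * 2, 1)
    for i in range(n_params):
        lines.append(f"  k{i} {rng.choice(['0.1', '1', '2', '10'])}")
    lines.append("end parameters")

    # molecule types
    mol_sites: dict[str, list[tuple[str, list[str]]]] = {}
    for i in range(spec.n_molecule_types):
        name = f"M{i}"
        n_sites = rng.randint(*spec.sites_per_molecule)
        sites = []
        for j in range(n_sites):
            sname = f"s{j}"
            if sites and rng.random() < spec.duplicate_site_p:
                sname = sites[-1][0]        # identical site
                states = list(sites[-1][1])
            else:
                n_states = rng.randint(*spec.states_per_site)
                states = _STATE_NAMES[:n_states] if n_states != 1 else \
                    _STATE_NAMES[:2]
            sites.append((sname, states))
        mol_sites[name] = sites
    lines.append("begin molecule types")
    for name, sites in mol_sites.items():
        decl = ",".join(s + "".join(f"~{t}" for t in states)
                        for s, states in sites)
        lines.append(f"  {name}({decl})")
    lines.append("end molecule types")

    if spec.compartment_depth > 0:
        lines.append("begin compartments")
        for d in range(spec.compartment_depth):
            parent = f" comp{d - 1}" if d > 0 else ""
            dim = 3 if d % 2 == 0 else 2
            lines.append(f"  comp{d} {dim} 1{parent}")
        lines.append("end compartments")

    def concrete(name: str) -> str:
        sites = mol_sites[name]
        body = ",".join(s + (f"~{states[0]}" if states else "")
                        for s, states in sites)
        return f"{name}({body})"

    lines.append("begin seed species")
    for name in mol_sites:
        tag = ""
        if spec.compartment_depth > 0:
            tag = f"@comp{rng.randrange(spec.compartment_depth)}:"
        lines.append(f"  {tag}{concrete(name)} 100")
    lines.append("end seed species")

    lines.append("begin observables")
    for name in mol_sites:
        lines.append(f"  Molecules tot_{name} {name}()")
    lines.append("end observables")

    def site_mention(name, si, bond=""):
        sname, states = mol_sites[name][si]
        state = f"~{rng.choice(states)}" if states and rng.random() < 0.7 \
            else ""
        return f"{sname}{state}{bond}"

    def with_context(name, primary_si, primary_text):
        """Molecule pattern text: the primary site plus optional context."""
        mentions = {primary_si: primary_text}
        for si in range(len(mol_sites[name])):
            if si != primary_si and rng.random() < 0.35 \
                    and mol_sites[name][si][0] != mol_sites[name][primary_si][0]:
                bond = rng.choice(["", "", "!+"])
                mentions[si] = site_mention(name, si, bond)
        body = ",".join(mentions[si] for si in sorted(mentions))
        return f"{name}({body})", mentions

    lines.append("begin reaction rules")
    kinds = ["bond", "state", "molecular"]
    r = 0
    attempts = 0
    while r < spec.n_rules and attempts < spec.n_rules * 20:
        attempts += 1
        kind = rng.choices(kinds, weights=spec.rule_mix)[0]
        label = f"rule{r}"
        reversible = rng.random() < spec.reversible_p
        arrow = "<->" if reversible else "->"
        rates = f"k{2 * r} , k{2 * r + 1}" if reversible else f"k{2 * r}"
        if kind == "bond":
            m1 = rng.choice(list(mol_sites))
            m2 = rng.choice(list(mol_sites))
            s1 = rng.randrange(len(mol_sites[m1]))
            s2 = rng.randrange(len(mol_sites[m2]))
            n1, men1 = with_context(m1, s1, site_mention(m1, s1))
            n2, men2 = with_context(m2, s2, site_mention(m2, s2))
            p1 = _rebody(m1, {**men1, s1: men1[s1] + "!1"}, mol_sites)
            p2 = _rebody(m2, {**men2, s2: men2[s2] + "!1"}, mol_sites)
            lines.append(f"  {label}: {n1} + {n2} {arrow} {p1}.{p2} {rates}")
        elif kind == "state":
            candidates = [(m, si) for m, sites in mol_sites.items()
                          for si, (_s, st) in enumerate(sites)
                          if len(st) >= 2]
            if not candidates:
                continue
            m, si = rng.choice(candidates)
            states = mol_sites[m][si][1]
            frm, to = rng.sample(states, 2)
            sname = mol_sites[m][si][0]
            lhs, men = with_context(m, si, f"{sname}~{frm}")
            rhs = _rebody(m, {**men, si: f"{sname}~{to}"}, mol_sites)
            if reversible:
                lines.append(f"  {label}: {lhs} {arrow} {rhs} {rates}")
            else:
                lines.append(f"  {label}: {lhs} -> {rhs} {rates}")
        else:
            m = rng.choice(list(mol_sites))
            if rng.random() < 0.5:
                lines.append(f"  {label}: {m}() -> 0 k{2 * r}")
            else:
                lines.append(f"  {label}: 0 -> {concrete(m)} k{2 * r}")
        r += 1
    lines.append("end reaction rules")
    text = "\n".join(lines) + "\n"
    return parse_model(text, name=f"random_{spec.seed}")


def _rebody(name, mentions: dict[int, str], mol_sites) -> str:
    body = ",".join(mentions[si] for si in sorted(mentions))
    return f"{name}({body})"


def random_model_text(spec: FixtureSpec) -> str:
    return serialize_model(random_model(spec))
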