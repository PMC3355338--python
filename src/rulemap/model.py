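"""Core data model for rule-based models written in BNGL.

A model is a structured document: parameters, molecule type declarations,
seed species, reaction rules, observables, compartments and actions.
Species and patterns are site graphs: molecules carry named components
(binding sites / modifiable domains), components carry an optional internal
state and a bond status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

# Bond status markers for pattern components.  A labeled bond is an ``int``.
FREE = "free"          # site explicitly unbound
BOUND_ANY = "any"      # "!+"  bound, partner unspecified
WILD = "wild"          # "!?"  bond status unconstrained

Bond = Union[int, str]


class BnglError(Exception):
    """Raised for syntactic or semantic problems; carries diagnostics."""

    def __init__(self, diagnostics):
        if isinstance(diagnostics, Diagnostic):
            diagnostics = [diagnostics]
        self.diagnostics = list(diagnostics)
        super().__init__("; ".join(str(d) for d in self.diagnostics))


@dataclass(frozen=True)
class Diagnostic:
    """A located error or warning message."""

    level: str              # "error" | "warning"
    message: str
    line: Optional[int] = None
    column: Optional[int] = None

    def __str__(self) -> str:
        loc = ""
        if self.line is not None:
            loc = f" (line {self.line}" + (
                f", col {self.column})" if self.column is not None else ")"
            )
        return f"{self.level}: {self.message}{loc}"


@dataclass
class ComponentPattern:
    name: str
    state: Optional[str] = None   # None = unspecified
    bond: Bond = WILD             # default: unconstrained

    def clone(self) -> "ComponentPattern":
        return ComponentPattern(self.name, self.state, self.bond)


@dataclass
class MoleculePattern:
    name: str
    components: list[ComponentPattern] = field(default_factory=list)
    compartment: Optional[str] = None

    def clone(self) -> "MoleculePattern":
        m = MoleculePattern(self.name, [c.clone() for c in self.components])
        m.compartment = self.compartment
        return m


@dataclass
class SpeciesPattern:
    """A (possibly disconnected) site-graph pattern over molecules.

    Bond labels pair component slots; :meth:`bonds` derives the pairing.
    A slot is addressed as ``(molecule_index, component_index)``.
    """

    molecules: list[MoleculePattern] = field(default_factory=list)
    compartment: Optional[str] = None

    def clone(self) -> "SpeciesPattern":
        p = SpeciesPattern([m.clone() for m in self.molecules])
        p.compartment = self.compartment
        return p

    def slots(self) -> Iterator[tuple[int, int, ComponentPattern]]:
        for mi, mol in enumerate(self.molecules):
            for ci, comp in enumerate(mol.components):
                yield mi, ci, comp

    def bonds(self) -> dict[int, list[tuple[int, int]]]:
        pairing: dict[int, list[tuple[int, int]]] = {}
        for mi, ci, comp in self.slots():
            if isinstance(comp.bond, int):
                pairing.setdefault(comp.bond, []).append((mi, ci))
        return pairing

    def bond_partner(self) -> dict[tuple[int, int], tuple[int, int]]:
        partner: dict[tuple[int, int], tuple[int, int]] = {}
        for ends in self.bonds().values():
            if len(ends) == 2:
                partner[ends[0]] = ends[1]
                partner[ends[1]] = ends[0]
        return partner

    def validate_bonds(self, where: str = "") -> list[Diagnostic]:
        """Every bond label must appear exactly twice within this pattern."""
        diags = []
        for label, ends in self.bonds().items():
            if len(ends) != 2:
                diags.append(Diagnostic(
                    "error",
                    f"bond label !{label} appears {len(ends)} time(s) "
                    f"in pattern{' ' + where if where else ''}; expected 2"))
        return diags

    def is_connected(self) -> bool:
        n = len(self.molecules)
        if n <= 1:
            return True
        adj: dict[int, set[int]] = {i: set() for i in range(n)}
        for ends in self.bonds().values():
            if len(ends) == 2:
                (a, _), (b, _) = ends
                adj[a].add(b)
                adj[b].add(a)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == n


@dataclass
class MoleculeType:
    name: str
    # (component name, allowed states); component names may repeat
    components: list[tuple[str, list[str]]] = field(default_factory=list)
    line: Optional[int] = None


@dataclass
class Compartment:
    name: str
    dimension: int
    volume: str
    parent: Optional[str] = None
    line: Optional[int] = None


@dataclass
class Observable:
    kind: str                    # "Molecules" | "Species"
    name: str
    patterns: list[SpeciesPattern] = field(default_factory=list)
    line: Optional[int] = None


@dataclass
class Action:
    verb: str
    arguments: dict[str, str] = field(default_factory=dict)
    raw: str = ""
    supported: bool = True
    line: Optional[int] = None


SUPPORTED_ACTIONS = {
    "generate_network", "simulate_ode", "simulate_ssa",
    "setConcentration", "setParameter", "saveConcentrations",
    "resetConcentrations", "parameter_scan",
}


@dataclass
class RxnRule:
    label: str
    reactants: list[SpeciesPattern] = field(default_factory=list)
    products: list[SpeciesPattern] = field(default_factory=list)
    rate_forward: str = "1"
    rate_reverse: Optional[str] = None
    reversible: bool = False
    line: Optional[int] = None

    def sides(self, direction: str) -> tuple[list[SpeciesPattern], list[SpeciesPattern]]:
        """Reactant and product pattern lists for a direction."""
        if direction == "forward":
            return self.reactants, self.products
        if direction == "reverse":
            if not self.reversible:
                raise ValueError(f"rule {self.label} is not reversible")
            return self.products, self.reactants
        raise ValueError(f"unknown direction {direction!r}")

    def rate(self, direction: str) -> str:
        return self.rate_forward if direction == "forward" else self.rate_reverse


@dataclass(frozen=True)
class RuleDir:
    """A unidirectional view of a rule: the influence-graph node identity."""

    label: str
    direction: str  # "forward" | "reverse"

    def __str__(self) -> str:
        return f"{self.label}_{'fwd' if self.direction == 'forward' else 'rev'}"


@dataclass
class Model:
    parameters: dict[str, str] = field(default_factory=dict)
    molecule_types: list[MoleculeType] = field(default_factory=list)
    compartments: list[Compartment] = field(default_factory=list)
    seed_species: list[tuple[SpeciesPattern, str]] = field(default_factory=list)
    observables: list[Observable] = field(default_factory=list)
    rules: list[RxnRule] = field(default_factory=list)
    actions: list[Action] = field(default_factory=list)
    name: str = "model"

    def molecule_type(self, name: str) -> Optional[MoleculeType]:
        for mt in self.molecule_types:
            if mt.name == name:
                return mt
        return None

    def rule(self, label: str) -> Optional[RxnRule]:
        for r in self.rules:
            if r.label == label:
                return r
        return None

    def rule_directions(self) -> list[RuleDir]:
        out = []
        for r in self.rules:
            out.append(RuleDir(r.label, "forward"))
            if r.reversible:
                out.append(RuleDir(r.label, "reverse"))
        return out
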