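"""Canonical BNGL emission: serialize a Model back to document text.

Block order is fixed (parameters, molecule types, compartments, seed
species, observables, reaction rules, actions) so equal models serialize
to equal documents.
"""

from __future__ import annotations

from .model import (
    BOUND_ANY, FREE, Model, MoleculePattern, MoleculeType, SpeciesPattern,
    WILD,
)


def component_to_str(comp) -> str:
    out = comp.name
    if comp.state is not None:
        out += f"~{comp.state}"
    if isinstance(comp.bond, int):
        out += f"!{comp.bond}"
    elif comp.bond == BOUND_ANY:
        out += "!+"
    elif comp.bond == WILD:
        out += "!?"
    # FREE: listed with no bond suffix
    return out


def molecule_to_str(mol: MoleculePattern, species_compartment=None) -> str:
    out = mol.name + "(" + ",".join(component_to_str(c)
                                    for c in mol.components) + ")"
    if mol.compartment and mol.compartment != species_compartment:
        out += f"@{mol.compartment}"
    return out


def pattern_to_str(pattern: SpeciesPattern) -> str:
    prefix = f"@{pattern.compartment}:" if pattern.compartment else ""
    return prefix + ".".join(
        molecule_to_str(m, pattern.compartment) for m in pattern.molecules)


def side_to_str(patterns: list[SpeciesPattern]) -> str:
    if not patterns:
        return "0"
    return " + ".join(pattern_to_str(p) for p in patterns)


def molecule_type_to_str(mt: MoleculeType) -> str:
    comps = []
    for cname, states in mt.components:
        comps.append(cname + "".join(f"~{s}" for s in states))
    return mt.name + "(" + ",".join(comps) + ")"


def rule_to_str(rule) -> str:
    arrow = "<->" if rule.reversible else "->"
    out = (f"{rule.label}: {side_to_str(rule.reactants)} {arrow} "
           f"{side_to_str(rule.products)} {rule.rate_forward}")
    if rule.reversible:
        out += f", {rule.rate_reverse}"
    return out


def serialize_model(model: Model) -> str:
    """Emit a BNGL document; ``parse_model`` on the result re-parses equal."""
    lines: list[str] = []

    lines.append("begin parameters")
    for name, expr in model.parameters.items():
        lines.append(f"  {name} {expr}")
    lines.append("end parameters")

    lines.append("begin molecule types")
    for mt in model.molecule_types:
        lines.append("  " + molecule_type_to_str(mt))
    lines.append("end molecule types")

    if model.compartments:
        lines.append("begin compartments")
        for c in model.compartments:
            tail = f" {c.parent}" if c.parent else ""
            lines.append(f"  {c.name} {c.dimension} {c.volume}{tail}")
        lines.append("end compartments")

    lines.append("begin seed species")
    for pat, amount in model.seed_species:
        lines.append(f"  {pattern_to_str(pat)} {amount}")
    lines.append("end seed species")

    lines.append("begin observables")
    for obs in model.observables:
        pats = " ".join(pattern_to_str(p) for p in obs.patterns)
        lines.append(f"  {obs.kind} {obs.name} {pats}")
    lines.append("end observables")

    lines.append("begin reaction rules")
    for rule in model.rules:
        lines.append("  " + rule_to_str(rule))
    lines.append("end reaction rules")

    for action in model.actions:
        if action.raw:
            lines.append(action.raw)
        else:
            args = ",".join(f"{k}=>{v}" for k, v in action.arguments.items())
            lines.append(f"{action.verb}({{{args}}})")

    return "\n".join(lines) + "\n"
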