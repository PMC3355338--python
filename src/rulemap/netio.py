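"""NET reaction-network file format (BioNetGen convention).

Blocks: parameters, species (1-based indices), reactions
(``index reactant_indices product_indices rate [#rule]``), groups
(observables as ``weight*species_index`` lists).  A truncated network
records the reason in a header comment.
"""

from __future__ import annotations

import re

from .model import BnglError, Diagnostic, RuleDir
from .network import NetSpecies, Reaction, ReactionNetwork
from .parser import parse_species_pattern


def write_net(net: ReactionNetwork) -> str:
    lines = ["# reaction network"]
    if net.truncated:
        lines.append(f"# truncated: {net.truncation_reason}")
    lines.append("begin parameters")
    for i, (name, expr) in enumerate(net.parameters.items(), start=1):
        lines.append(f"  {i} {name} {expr}")
    lines.append("end parameters")
    lines.append("begin species")
    for sp in net.species:
        lines.append(f"  {sp.index} {sp.canonical} {sp.initial_expr}")
    lines.append("end species")
    lines.append("begin reactions")
    for rxn in net.reactions:
        r = ",".join(str(i) for i in rxn.reactants) or "0"
        p = ",".join(str(i) for i in rxn.products) or "0"
        lines.append(f"  {rxn.index} {r} {p} {rxn.rate_text()} "
                     f"#{rxn.rule}")
    lines.append("end reactions")
    lines.append("begin groups")
    for i, (name, entries) in enumerate(net.observable_groups.items(),
                                        start=1):
        body = ",".join(
            f"{idx}" if w == 1 else f"{_fmt_w(w)}*{idx}"
            for idx, w in entries)
        lines.append(f"  {i} {name} {body}")
    lines.append("end groups")
    return "\n".join(lines) + "\n"


def _fmt_w(w: float) -> str:
    return f"{int(w)}" if float(w).is_integer() else f"{w:g}"


_RULE_TAG = re.compile(r"#\s*(\S+?)_(fwd|rev)\s*$")


def read_net(text: str) -> ReactionNetwork:
    net = ReactionNetwork()
    block = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("# truncated:"):
            net.truncated = True
            net.truncation_reason = line.split(":", 1)[1].strip()
            continue
        rule_dir = None
        m = _RULE_TAG.search(line)
        if m:
            rule_dir = RuleDir(
                m.group(1), "forward" if m.group(2) == "fwd" else "reverse")
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        low = line.lower()
        if low.startswith("begin"):
            block = low[5:].strip()
            continue
        if low.startswith("end"):
            block = None
            continue
        fields = line.split()
        if block == "parameters":
            if len(fields) < 3:
                raise BnglError(Diagnostic(
                    "error", f"malformed parameter line: {raw!r}", lineno))
            net.parameters[fields[1]] = " ".join(fields[2:])
        elif block == "species":
            if len(fields) < 2:
                raise BnglError(Diagnostic(
                    "error", f"malformed species line: {raw!r}", lineno))
            idx = int(fields[0])
            try:
                pattern = parse_species_pattern(fields[1], lineno)
            except BnglError as e:
                raise BnglError(Diagnostic(
                    "error", f"malformed species string at index {idx}: "
                    f"{e.diagnostics[0].message}", lineno)) from e
            initial = fields[2] if len(fields) > 2 else "0"
            if idx != len(net.species) + 1:
                raise BnglError(Diagnostic(
                    "error", f"species index {idx} out of order", lineno))
            net.species.append(NetSpecies(idx, pattern, fields[1], initial))
        elif block == "reactions":
            if len(fields) < 4:
                raise BnglError(Diagnostic(
                    "error", f"malformed reaction line: {raw!r}", lineno))
            idx = int(fields[0])
            reac = tuple(int(i) for i in fields[1].split(",") if i != "0")
            prod = tuple(int(i) for i in fields[2].split(",") if i != "0")
            rate = " ".join(fields[3:])
            factor = 1.0
            fm = re.match(r"^([0-9.eE+-]+)\*\((.*)\)$", rate)
            if fm:
                factor = float(fm.group(1))
                rate = fm.group(2)
            for i in reac + prod:
                if not 1 <= i <= 10 ** 9:
                    raise BnglError(Diagnostic(
                        "error", f"species index {i} out of range", lineno))
            net.reactions.append(Reaction(
                idx, reac, prod, rate, factor,
                rule_dir or RuleDir(f"rxn{idx}", "forward")))
        elif block == "groups":
            if len(fields) < 2:
                raise BnglError(Diagnostic(
                    "error", f"malformed group line: {raw!r}", lineno))
            name = fields[1]
            entries = []
            if len(fields) > 2:
                for item in fields[2].split(","):
                    if "*" in item:
                        w, i = item.split("*", 1)
                        entries.append((int(i), float(w)))
                    else:
                        entries.append((int(item), 1.0))
            net.observable_groups[name] = entries
    n = len(net.species)
    for rxn in net.reactions:
        for i in rxn.reactants + rxn.products:
            if i > n:
                raise BnglError(Diagnostic(
                    "error", f"reaction {rxn.index} references species {i} "
                    f"but only {n} species are defined"))
    for name, entries in net.observable_groups.items():
        for i, _w in entries:
            if i > n:
                raise BnglError(Diagnostic(
                    "error", f"group {name} references species {i} "
                    f"out of range"))
    return net
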