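"""BNGL text parser.

Accepts the common BNGL 2.x core: block structure (``begin``/``end``),
``#`` comments, ``\\`` line continuation, optional numeric or ``label:``
prefixes on block entries, and the standard pattern syntax
(``A(x!1,y~P).B(z!1)``, bond wildcards ``!+``/``!?``, state wildcard
``~?``, compartment tags ``@C:`` and ``@C`` which are normalized to one
internal form).  Anything outside that core is reported, never silently
dropped.
"""

from __future__ import annotations

import re
from typing import Optional

from .model import (
    Action, BnglError, BOUND_ANY, Compartment, ComponentPattern, Diagnostic,
    FREE, Model, MoleculePattern, MoleculeType, Observable, RxnRule,
    SpeciesPattern, SUPPORTED_ACTIONS, WILD,
)

_NAME = r"[A-Za-z_][A-Za-z0-9_]*"
_BLOCK_ALIASES = {
    "parameters": "parameters",
    "molecule types": "molecule types",
    "compartments": "compartments",
    "species": "seed species",
    "seed species": "seed species",
    "observables": "observables",
    "reaction rules": "reaction rules",
    "actions": "actions",
    "model": "model",
}


def _logical_lines(text: str) -> list[tuple[int, str]]:
    """Comment-stripped, continuation-joined lines with 1-based numbers."""
    out = []
    pending = ""
    pending_line = None
    for i, raw in enumerate(text.replace("\r\n", "\n").split("\n"), start=1):
        line = raw.split("#", 1)[0]
        if line.rstrip().endswith("\\"):
            pending += line.rstrip()[:-1] + " "
            if pending_line is None:
                pending_line = i
            continue
        full = pending + line
        lineno = pending_line if pending_line is not None else i
        pending, pending_line = "", None
        if full.strip():
            out.append((lineno, full.strip()))
    if pending.strip():
        out.append((pending_line, pending.strip()))
    return out


# ---------------------------------------------------------------------------
# Pattern parsing


class _Scanner:
    def __init__(self, text: str, line: Optional[int] = None):
        self.text = text
        self.pos = 0
        self.line = line

    def error(self, message: str) -> BnglError:
        return BnglError(Diagnostic("error", f"{message} in {self.text!r}",
                                    self.line, self.pos + 1))

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def eat(self, ch: str) -> bool:
        if self.text.startswith(ch, self.pos):
            self.pos += len(ch)
            return True
        return False

    def name(self) -> str:
        m = re.match(_NAME, self.text[self.pos:])
        if not m:
            raise self.error("expected identifier")
        self.pos += m.end()
        return m.group(0)

    def number(self) -> int:
        m = re.match(r"\d+", self.text[self.pos:])
        if not m:
            raise self.error("expected bond label number")
        self.pos += m.end()
        return int(m.group(0))


def _parse_component(sc: _Scanner, declaration: bool) -> tuple[str, list[str], Optional[str], object]:
    """Returns (name, declared_states, pattern_state, bond)."""
    cname = sc.name()
    states: list[str] = []
    state: Optional[str] = None
    bond: object = FREE if not declaration else WILD
    while sc.peek() == "~":
        sc.eat("~")
        if sc.eat("?"):
            state = None
        else:
            s = sc.name() if not re.match(r"\d", sc.peek() or "x") else None
            if s is None:  # numeric state like ~0
                m = re.match(r"\d+", sc.text[sc.pos:])
                sc.pos += m.end()
                s = m.group(0)
            states.append(s)
            state = s
    if not declaration and len(states) > 1:
        raise sc.error(f"component {cname} lists multiple states in a pattern")
    while sc.peek() == "!":
        sc.eat("!")
        if sc.eat("+"):
            bond = BOUND_ANY
        elif sc.eat("?"):
            bond = WILD
        else:
            bond = sc.number()
    return cname, states, state, bond


def _parse_molecule(sc: _Scanner, declaration: bool = False):
    mname = sc.name()
    comps = []
    if sc.eat("("):
        if not sc.eat(")"):
            while True:
                comps.append(_parse_component(sc, declaration))
                if sc.eat(","):
                    continue
                if sc.eat(")"):
                    break
                raise sc.error("expected ',' or ')' in molecule")
    compartment = None
    if sc.eat("@"):
        compartment = sc.name()
    return mname, comps, compartment


def parse_species_pattern(text: str, line: Optional[int] = None) -> SpeciesPattern:
    """Parse one species pattern, e.g. ``@PM:Rec(a!1,b).Lig(l!1,l)``."""
    sc = _Scanner("".join(text.split()), line)
    pattern = SpeciesPattern()
    if sc.eat("@"):
        pattern.compartment = sc.name()
        sc.eat("::") or sc.eat(":")
    while True:
        mname, comps, mcomp = _parse_molecule(sc)
        mol = MoleculePattern(mname)
        mol.compartment = mcomp or pattern.compartment
        for cname, _states, state, bond in comps:
            mol.components.append(ComponentPattern(cname, state, bond))
        pattern.molecules.append(mol)
        if sc.eat("."):
            continue
        break
    if sc.pos != len(sc.text):
        raise sc.error("trailing characters after species pattern")
    diags = pattern.validate_bonds(where=text)
    if diags:
        raise BnglError([Diagnostic(d.level, d.message, line) for d in diags])
    return pattern


def parse_molecule_type(text: str, line: Optional[int] = None) -> MoleculeType:
    sc = _Scanner("".join(text.split()), line)
    mname, comps, _ = _parse_molecule(sc, declaration=True)
    if sc.pos != len(sc.text):
        raise sc.error("trailing characters after molecule type")
    mt = MoleculeType(mname, line=line)
    for cname, states, _state, _bond in comps:
        if len(states) != len(set(states)):
            raise BnglError(Diagnostic(
                "error", f"duplicate state in {mname}.{cname}", line))
        mt.components.append((cname, states))
    return mt


def _split_top(text: str, sep: str) -> list[str]:
    """Split on a separator at parenthesis depth 0 (skips e+/e- exponents)."""
    parts, depth, start = [], 0, 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == sep and depth == 0:
            if sep == "+" and i > 0 and text[i - 1] in "eE" \
                    and i + 1 < len(text) and text[i + 1].isdigit():
                continue
            parts.append(text[start:i])
            start = i + 1
    parts.append(text[start:])
    return parts


def _parse_side(text: str, line: Optional[int]) -> list[SpeciesPattern]:
    patterns = []
    for chunk in _split_top(text, "+"):
        chunk = chunk.strip()
        if chunk in ("0", ""):   # null species: no pattern
            continue
        patterns.append(parse_species_pattern(chunk, line))
    return patterns


_LABEL_PREFIX = re.compile(rf"^(?:(\d+)|({_NAME})\s*:)\s+")
_RULE_MODIFIERS = ("DeleteMolecules", "TotalRate", "MoveConnected")


def _parse_rule(text: str, line: int, auto_label: str,
                warnings: list[Diagnostic]) -> RxnRule:
    label = auto_label
    m = re.match(rf"^({_NAME})\s*:\s*", text)
    if m:
        label, text = m.group(1), text[m.end():]
    reversible = "<->" in text
    lhs, rhs = re.split(r"<->|->", text, maxsplit=1)
    rule = RxnRule(label, line=line, reversible=reversible)
    rule.reactants = _parse_side(lhs.strip(), line)

    # products followed by rate expression(s); products are '+'-separated
    chunks = _split_top(rhs.strip(), "+")
    last = chunks[-1].strip()
    fields = last.split(None, 1)
    if not fields:
        raise BnglError(Diagnostic("error", "missing product/rate", line))
    prod_text = " + ".join(c.strip() for c in chunks[:-1] + [fields[0]])
    rate_text = fields[1].strip() if len(fields) > 1 else ""
    for mod in _RULE_MODIFIERS:
        if re.search(rf"\b{mod}\b", rate_text):
            warnings.append(Diagnostic(
                "warning", f"rule modifier {mod} not supported; ignored "
                f"(rule {label})", line))
            rate_text = re.sub(rf"\b{mod}\b", "", rate_text).strip()
    rule.products = _parse_side(prod_text, line)
    rates = [r.strip() for r in _split_top(rate_text, ",") if r.strip()]
    if reversible:
        if len(rates) != 2:
            raise BnglError(Diagnostic(
                "error", f"reversible rule {label} needs 2 rates, got "
                f"{len(rates)}", line))
        rule.rate_forward, rule.rate_reverse = rates
    else:
        if len(rates) != 1:
            raise BnglError(Diagnostic(
                "error", f"rule {label} needs 1 rate, got {len(rates)}", line))
        rule.rate_forward = rates[0]
    return rule


_ACTION_RE = re.compile(rf"^({_NAME})\s*\(\s*(.*?)\s*\)\s*;?\s*$", re.S)


def _parse_action(text: str, line: int) -> Optional[Action]:
    m = _ACTION_RE.match(text)
    if not m:
        return None
    verb, argtext = m.group(1), m.group(2)
    argtext = argtext.strip()
    if argtext.startswith("{") and argtext.endswith("}"):
        argtext = argtext[1:-1]
    args: dict[str, str] = {}
    for item in _split_top(argtext, ","):
        item = item.strip()
        if not item:
            continue
        if "=>" in item:
            k, v = item.split("=>", 1)
        elif "=" in item:
            k, v = item.split("=", 1)
        else:
            k, v = str(len(args)), item
        args[k.strip()] = v.strip().strip('"')
    return Action(verb, args, raw=text, supported=verb in SUPPORTED_ACTIONS,
                  line=line)


# ---------------------------------------------------------------------------
# Model parsing


def parse_model(text: str, name: str = "model", validate: bool = True) -> Model:
    """Parse a complete BNGL document into a :class:`Model`.

    Raises :class:`BnglError` on syntax errors and (when ``validate``) on
    semantic errors; warnings are collected on ``model.warnings``.
    """
    model = Model(name=name)
    warnings: list[Diagnostic] = []
    lines = _logical_lines(text)
    block: Optional[str] = None
    counters = {"rule": 0}

    for lineno, line in lines:
        low = line.lower()
        if low.startswith("begin"):
            bname = line[5:].strip().lower()
            if bname == "model":
                continue
            if bname not in _BLOCK_ALIASES:
                warnings.append(Diagnostic(
                    "warning", f"unknown block {bname!r} ignored", lineno))
                block = f"?{bname}"
            else:
                block = _BLOCK_ALIASES[bname]
            continue
        if low.startswith("end"):
            block = None
            continue
        if block is None or block == "actions":
            action = _parse_action(line, lineno)
            if action is not None:
                if not action.supported:
                    warnings.append(Diagnostic(
                        "warning", f"unsupported action {action.verb!r} "
                        "preserved but will not execute", lineno))
                model.actions.append(action)
                continue
            if block == "actions":
                raise BnglError(Diagnostic(
                    "error", f"cannot parse action: {line!r}", lineno))
            warnings.append(Diagnostic(
                "warning", f"text outside any block ignored: {line!r}", lineno))
            continue
        if block.startswith("?"):
            continue

        stripped = line
        m = _LABEL_PREFIX.match(stripped)
        explicit_label = None
        if m and block in ("parameters", "molecule types", "seed species",
                           "observables", "reaction rules"):
            # numeric index or "name:" label prefix
            if m.group(2) and block != "reaction rules":
                explicit_label = m.group(2)
            if not (block == "reaction rules" and m.group(2)):
                stripped = stripped[m.end():]
            if m.group(2) and block == "reaction rules":
                pass  # rule labels handled inside _parse_rule

        try:
            if block == "parameters":
                fields = re.split(r"[=\s]+", stripped, maxsplit=1)
                if len(fields) != 2:
                    raise BnglError(Diagnostic(
                        "error", f"cannot parse parameter: {line!r}", lineno))
                pname, pexpr = fields[0], fields[1].strip()
                if pname in model.parameters:
                    raise BnglError(Diagnostic(
                        "error", f"duplicate parameter {pname!r}", lineno))
                model.parameters[pname] = pexpr
            elif block == "molecule types":
                mt = parse_molecule_type(stripped, lineno)
                if model.molecule_type(mt.name) is not None:
                    raise BnglError(Diagnostic(
                        "error", f"duplicate molecule type {mt.name!r}", lineno))
                model.molecule_types.append(mt)
            elif block == "compartments":
                fields = stripped.split()
                if len(fields) not in (3, 4):
                    raise BnglError(Diagnostic(
                        "error", f"cannot parse compartment: {line!r}", lineno))
                model.compartments.append(Compartment(
                    fields[0], int(fields[1]), fields[2],
                    fields[3] if len(fields) == 4 else None, line=lineno))
            elif block == "seed species":
                fields = stripped.split(None, 1)
                ptext = fields[0].lstrip("$")
                amount = fields[1].strip() if len(fields) > 1 else "0"
                pat = parse_species_pattern(ptext, lineno)
                model.seed_species.append((pat, amount))
            elif block == "observables":
                fields = stripped.split(None, 2)
                if len(fields) < 3:
                    raise BnglError(Diagnostic(
                        "error", f"cannot parse observable: {line!r}", lineno))
                kind, oname, ptext = fields
                if kind not in ("Molecules", "Species"):
                    raise BnglError(Diagnostic(
                        "error", f"unknown observable kind {kind!r}", lineno))
                pats = []
                for chunk in _split_top(ptext, ","):
                    for piece in chunk.split():
                        pats.append(parse_species_pattern(piece, lineno))
                model.observables.append(
                    Observable(kind, oname, pats, line=lineno))
            elif block == "reaction rules":
                counters["rule"] += 1
                auto = explicit_label or f"R{counters['rule']}"
                model.rules.append(
                    _parse_rule(stripped, lineno, auto, warnings))
        except BnglError:
            raise
        except Exception as exc:  # wrap stray failures with a location
            raise BnglError(Diagnostic(
                "error", f"{exc} while parsing {line!r}", lineno)) from exc

    model.warnings = warnings  # type: ignore[attr-defined]
    if validate:
        errors = [d for d in validate_model(model) if d.level == "error"]
        if errors:
            raise BnglError(errors)
    return model


# ---------------------------------------------------------------------------
# Semantic validation


def _check_pattern(pattern: SpeciesPattern, model: Model, where: str,
                   line, diags: list[Diagnostic]) -> None:
    if not model.molecule_types:
        return
    for mol in pattern.molecules:
        mt = model.molecule_type(mol.name)
        if mt is None:
            diags.append(Diagnostic(
                "error", f"undeclared molecule {mol.name!r} in {where}", line))
            continue
        declared: dict[str, list[list[str]]] = {}
        for cname, states in mt.components:
            declared.setdefault(cname, []).append(states)
        used: dict[str, int] = {}
        for comp in mol.components:
            used[comp.name] = used.get(comp.name, 0) + 1
            if comp.name not in declared:
                diags.append(Diagnostic(
                    "error", f"undeclared component {mol.name}.{comp.name} "
                    f"in {where}", line))
                continue
            if used[comp.name] > len(declared[comp.name]):
                diags.append(Diagnostic(
                    "error", f"component {comp.name!r} used more often than "
                    f"declared in {mol.name} in {where}", line))
            elif comp.state is not None:
                allowed = declared[comp.name][used[comp.name] - 1]
                all_states = {s for states in declared[comp.name]
                              for s in states}
                if comp.state not in all_states:
                    diags.append(Diagnostic(
                        "error", f"undeclared state {comp.state!r} for "
                        f"{mol.name}.{comp.name} in {where}", line))
                del allowed


def validate_model(model: Model) -> list[Diagnostic]:
    """Semantic checks across blocks; returns diagnostics (errors+warnings)."""
    diags: list[Diagnostic] = []

    # parameter dependency cycles
    from . import expr as _expr
    for pname in model.parameters:
        try:
            _expr.evaluate(pname, model.parameters)
        except BnglError as e:
            for d in e.diagnostics:
                if "cyclic" in d.message or "bad token" in d.message:
                    diags.append(d)
                # undefined references may be rate-law functions; warn
                elif "undefined" in d.message:
                    diags.append(Diagnostic(
                        "warning", f"parameter {pname}: {d.message}"))

    # compartment forest
    names = {c.name for c in model.compartments}
    for c in model.compartments:
        if c.parent is not None and c.parent not in names:
            diags.append(Diagnostic(
                "error", f"compartment {c.name} has unknown parent "
                f"{c.parent!r}", c.line))
    seen: dict[str, Optional[str]] = {c.name: c.parent
                                      for c in model.compartments}
    for c in model.compartments:
        hops, cur = 0, c.name
        while cur is not None and hops <= len(seen):
            cur = seen.get(cur)
            hops += 1
        if cur is not None or hops > len(seen):
            diags.append(Diagnostic(
                "error", f"compartment parent cycle involving {c.name}",
                c.line))
            break

    for i, (pat, _amt) in enumerate(model.seed_species):
        _check_pattern(pat, model, f"seed species {i + 1}", None, diags)
    for obs in model.observables:
        for pat in obs.patterns:
            _check_pattern(pat, model, f"observable {obs.name}", obs.line,
                           diags)
    onames = [o.name for o in model.observables]
    if len(onames) != len(set(onames)):
        diags.append(Diagnostic("error", "duplicate observable names"))
    for rule in model.rules:
        for pat in rule.reactants + rule.products:
            _check_pattern(pat, model, f"rule {rule.label}", rule.line, diags)
    return diags
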