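"""Embedding, rule deltas, classification and canonical labeling."""

import itertools
import random

import pytest

from oracles import (
    count_embeddings_oracle, delta_oracle, isomorphic_oracle,
)
from rulemap.fixtures import FixtureSpec, random_model
from rulemap.model import BnglError
from rulemap.network import apply_rule_instance, _RuleApplicator
from rulemap.parser import parse_model, parse_species_pattern as P
from rulemap.patterns import (
    canonical_form, classify_rule, compute_delta, embed, is_concrete,
)


def _rule(text, types="A(x,y~U~P)\n  B(z)\n  Rec(a,b)\n  Lyn(U,SH2)"):
    doc = (f"begin molecule types\n  {types}\nend molecule types\n"
           f"begin reaction rules\n  r: {text}\nend reaction rules\n")
    return parse_model(doc).rules[0]


class TestEmbedding:
    def test_identity_embedding_is_unique(self):
        assert len(embed(P("Lyn(U,SH2)"), P("Lyn(U,SH2)"))) == 1

    def test_free_site_cannot_match_bound_site(self):
        assert embed(P("A(x)"), P("A(x!1).A(x!1)")) == []

    def test_unlisted_components_are_unconstrained(self):
        assert len(embed(P("A()"), P("A(x!1).A(x!1)"))) == 2

    def test_wildcards(self):
        dimer = P("A(x!1).A(x!1)")
        assert len(embed(P("A(x!+)"), dimer)) == 2
        assert len(embed(P("A(x!?)"), dimer)) == 2

    def test_identical_sites_match_either_slot(self):
        target = P("Lig(l!1,l).Rec(a!1,b)")
        assert len(embed(P("Lig(l)"), target)) == 1      # the free slot
        assert len(embed(P("Lig(l!+)"), target)) == 1    # the bound slot

    def test_reflexive_on_concrete_species(self):
        for text in ["A(x,y~U)", "A(x!1,y~P).B(z!1)", "B(z)"]:
            sp = P(text)
            assert len(embed(sp, sp)) >= 1

    def test_embedding_composes(self):
        p = P("Lyn(SH2)")
        q = P("Lyn(SH2,U)")
        s = P("Lyn(SH2,U~?)")  # treated as concrete-ish target
        assert embed(p, q) and embed(q, s) and embed(p, s)

    @pytest.mark.parametrize("seed", range(40))
    def test_counts_match_exhaustive_oracle(self, seed):
        """Embedding counts equal brute-force enumeration over all
        molecule injections with constraint checking (<=5 molecules)."""
        rng = random.Random(seed)
        model = random_model(FixtureSpec(seed=seed, n_molecule_types=2,
                                         sites_per_molecule=(1, 2),
                                         n_rules=3))
        from rulemap.network import generate_network
        net = generate_network(model, max_iter=4, max_agg=5)
        species = [s.pattern for s in net.species][:6]
        patterns = [p for r in model.rules
                    for p in r.reactants + r.products]
        for pat in patterns[:6]:
            for sp in species:
                assert len(embed(pat, sp)) == \
                    count_embeddings_oracle(pat, sp), \
                    f"{pat} into {sp.molecules}"
        del rng


class TestDelta:
    def test_lyn_center_is_the_new_bond_and_context_keeps_free_u(self):
        rule = _rule("Rec(b) + Lyn(SH2,U) <-> Rec(b!1).Lyn(SH2!1,U) 1, 1")
        d = compute_delta(rule, "forward")
        assert {el[0] for el in d.center} == {"bond+"}
        (el,) = d.center
        assert el[1:] == ((0, 0), (1, 0))       # Rec.b -- Lyn.SH2
        assert ("free", (1, 1)) in d.context     # Lyn.U stays free
        assert ("mol", 0) in d.context and ("mol", 1) in d.context

    def test_incorrect_variant_lacks_the_context_element(self):
        rule = _rule("Rec(b) + Lyn(SH2) <-> Rec(b!1).Lyn(SH2!1) 1, 1")
        d = compute_delta(rule, "forward")
        assert not any(el[0] == "free" and el[1] == (1, 1)
                       for el in d.context)

    def test_identity_rule_has_empty_center(self):
        rule = _rule("A(x) -> A(x) 1")
        d = compute_delta(rule, "forward")
        assert d.center == set()
        assert ("free", (0, 0)) in d.context

    def test_forward_and_reverse_centers_are_inverses(self):
        rule = _rule("Rec(b) + Lyn(SH2,U) <-> Rec(b!1).Lyn(SH2!1,U) 1, 1")
        fwd = compute_delta(rule, "forward")
        rev = compute_delta(rule, "reverse")
        assert {el[0] for el in fwd.center} == {"bond+"}
        assert {el[0] for el in rev.center} == {"bond-"}
        # same bond endpoints (Rec.b -- Lyn.SH2) on both directions
        assert {el[1:] for el in fwd.center} == \
            {el[1:] for el in rev.center} == {((0, 0), (1, 0))}

    def test_state_change_and_creation_deletion(self):
        d = compute_delta(_rule("A(y~U) -> A(y~P) 1"))
        assert any(el[0] == "state" and el[2:] == ("U", "P")
                   for el in d.center)
        d = compute_delta(_rule("A() -> 0 1"))
        assert d.center == {("mol-", 0)}
        d = compute_delta(_rule("0 -> B(z) 1"))
        assert d.center == {("mol+", 0)}

    def test_bound_any_to_labeled_bond_is_rejected(self):
        with pytest.raises(BnglError):
            compute_delta(_rule("A(x!+) + B(z) -> A(x!1).B(z!1) 1"))

    @pytest.mark.parametrize("seed", range(40))
    def test_center_matches_graph_diff_oracle(self, seed):
        model = random_model(FixtureSpec(seed=seed + 500, n_rules=4))
        for rule in model.rules:
            directions = ["forward"] + (["reverse"] if rule.reversible
                                        else [])
            for direction in directions:
                d = compute_delta(rule, direction)
                oracle = delta_oracle(rule, direction)
                assert oracle is not None
                center, context = oracle
                assert d.center == center, (rule.label, direction)
                # implementation context additionally carries ("mol", i)
                assert {el for el in d.context} == \
                    {el for el in context} | {("mol", i)
                                              for el in context
                                              if el[0] == "mol"
                                              for i in [el[1]]}


class TestClassification:
    @pytest.mark.parametrize("text,expected", [
        ("Rec(b) + Lyn(SH2,U) <-> Rec(b!1).Lyn(SH2!1,U) 1, 1", "bond_rule"),
        ("A(y~U) -> A(y~P) 1", "state_change_rule"),
        ("A() -> 0 1", "molecular_rule"),
        ("0 -> B(z) 1", "molecular_rule"),
        ("A(x,y~U) + B(z) -> A(x!1,y~P).B(z!1) 1", "mixed"),
        ("A(x) -> A(x) 1", "null_rule"),
    ])
    def test_categories(self, text, expected):
        assert classify_rule(_rule(text)) == expected


class TestCanonicalization:
    def test_permuted_component_order(self):
        assert canonical_form(P("A(x,y~P)")) == canonical_form(P("A(y~P,x)"))

    def test_symmetric_dimer_molecule_order(self):
        assert canonical_form(P("A(x!1,y~U).A(x!1,y~P)")) == \
            canonical_form(P("A(x!2,y~P).A(x!2,y~U)"))

    def test_ring_vs_chain_distinct(self):
        r3 = P("Lig(l!1,l!2).Lig(l!2,l!3).Lig(l!3,l!1)")
        c3 = P("Lig(l,l!1).Lig(l!1,l!2).Lig(l!2,l)")
        assert canonical_form(r3) != canonical_form(c3)

    def test_disconnected_input_is_an_error(self):
        with pytest.raises(BnglError):
            canonical_form(P("A(x).B(z)"))

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_isomorphism_oracle(self, seed):
        """On generated species up to 6 molecules, equal canonical forms
        exactly characterize isomorphism (all-pairs check)."""
        model = random_model(FixtureSpec(seed=seed + 100,
                                         n_molecule_types=2,
                                         sites_per_molecule=(1, 2),
                                         n_rules=4))
        from rulemap.network import generate_network
        net = generate_network(model, max_iter=4, max_agg=6)
        species = [s.pattern for s in net.species][:8]
        for a, b in itertools.combinations_with_replacement(species, 2):
            same = canonical_form(a) == canonical_form(b)
            assert same == isomorphic_oracle(a, b)

    def test_symmetric_presentations_of_a_ring(self):
        mols = ["Lig(l!1,l!2)", "Lig(l!2,l!3)", "Lig(l!3,l!1)"]
        forms = {canonical_form(P(".".join(p)))
                 for p in itertools.permutations(mols)}
        assert len(forms) == 1


class TestRuleApplication:
    def test_forward_then_reverse_restores_species(self):
        """Applying a reversible rule forward then backward returns an
        isomorphic species (round-trip at the rewriting level)."""
        doc = """
begin molecule types
  A(x,y~U~P)
end molecule types
begin reaction rules
  r: A(x) + A(x) <-> A(x!1).A(x!1) 1, 1
end reaction rules
"""
        model = parse_model(doc)
        rule = model.rules[0]
        fwd = _RuleApplicator(rule, "forward", model)
        rev = _RuleApplicator(rule, "reverse", model)
        a = P("A(x,y~U)")
        b = P("A(x,y~P)")
        (dimer,) = apply_rule_instance(
            fwd, [a, b], [embed(fwd.patterns[0], a)[0],
                          embed(fwd.patterns[1], b)[0]])
        assert len(dimer.molecules) == 2
        halves = apply_rule_instance(
            rev, [dimer], [embed(rev.patterns[0], dimer)[0]])
        assert sorted(canonical_form(h) for h in halves) == \
            sorted([canonical_form(a), canonical_form(b)])

    def test_is_concrete(self):
        model = parse_model(
            "begin molecule types\n  A(x,y~U~P)\nend molecule types\n")
        assert is_concrete(P("A(x,y~U)"), model.molecule_types)
        assert not is_concrete(P("A(x)"), model.molecule_types)
        assert not is_concrete(P("A(x!+,y~U)"), model.molecule_types)
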