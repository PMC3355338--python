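"""Rule influence: pattern relations, graph construction, ordering."""

import pytest

from oracles import pattern_relation_oracle
from rulemap.fixtures import FixtureSpec, lyn_fixture, random_model
from rulemap.influence import (
    _center_on_side, build_influence_graph, linear_order, pattern_relation,
    rule_influence,
)
from rulemap.model import RuleDir
from rulemap.parser import parse_model, parse_species_pattern as P
from rulemap.patterns import compute_delta


def _two_lyn_rules():
    return parse_model("""
begin molecule types
  Rec(a,b)
  Lyn(U,SH2)
end molecule types
begin reaction rules
  LynSH2: Rec(b) + Lyn(SH2,U) <-> Rec(b!1).Lyn(SH2!1,U) 1, 1
  LynU: Rec(b) + Lyn(U,SH2) <-> Rec(b!1).Lyn(SH2,U!1) 1, 1
end reaction rules
""")


class TestPatternRelation:
    def test_lyn_reactant_full_match_on_center(self):
        model = _two_lyn_rules()
        d1 = compute_delta(model.rule("LynSH2"), "forward")
        center = _center_on_side(d1, "reactant")
        # Lyn pattern of LynU onto Lyn pattern of LynSH2 (pattern index 1)
        rel = pattern_relation(model.rule("LynU").reactants[1],
                               model.rule("LynSH2").reactants[1],
                               center.slots.get(1, set()),
                               center.mols.get(1, set()))
        assert rel == "full"

    def test_disjoint_molecules_no_relation(self):
        center_slots = {(0, 0)}
        assert pattern_relation(P("B(z)"), P("A(x)"), center_slots,
                                set()) == "none"

    def test_state_conflict_downgrades_to_partial(self):
        # center on x; y states conflict, so no full match
        p1 = P("A(x,y~U)")
        p2 = P("A(x,y~P)")
        assert pattern_relation(p2, p1, {(0, 0)}, set()) == "partial"
        assert pattern_relation_oracle(p2, p1, {(0, 0)}, set()) == "partial"

    def test_context_only_overlap_is_none(self):
        # overlap exists but does not touch the center slot
        p1 = P("A(x,y~U)")
        p2 = P("A(y~U)")
        assert pattern_relation(p2, p1, {(0, 0)}, set()) == "none"


class TestRuleInfluence:
    def test_mutual_full_inhibition_of_the_forward_lyn_rules(self):
        model = _two_lyn_rules()
        s, u = model.rule("LynSH2"), model.rule("LynU")
        assert ("inhibition", "full") in rule_influence(s, "forward", u,
                                                        "forward")
        assert ("inhibition", "full") in rule_influence(u, "forward", s,
                                                        "forward")

    def test_unbinding_fully_activates_both_binding_rules(self):
        model = _two_lyn_rules()
        s, u = model.rule("LynSH2"), model.rule("LynU")
        for src in (s, u):
            for dst in (s, u):
                assert ("activation", "full") in rule_influence(
                    src, "reverse", dst, "forward")

    def test_disjoint_rules_have_no_influence(self, two_group_model):
        bind = two_group_model.rule("bindAB")
        flip = two_group_model.rule("flipC")
        assert rule_influence(bind, "forward", flip, "forward") == set()

    def test_hand_derived_two_rule_table(self):
        """Full influence table of the two-rule Lyn model, derived by
        tracing the two-step matching procedure by hand."""
        model = _two_lyn_rules()
        graph = build_influence_graph(model)
        got = {}
        for src, dst, pol, strength in graph.edges:
            got.setdefault((str(src), str(dst)), set()).add((pol, strength))
        expected = {
            ("LynSH2_fwd", "LynU_fwd"): {("inhibition", "full")},
            ("LynU_fwd", "LynSH2_fwd"): {("inhibition", "full")},
            ("LynSH2_fwd", "LynSH2_rev"): {("activation", "full")},
            ("LynSH2_rev", "LynSH2_fwd"): {("activation", "full")},
            ("LynU_fwd", "LynU_rev"): {("activation", "full")},
            ("LynU_rev", "LynU_fwd"): {("activation", "full")},
            ("LynSH2_rev", "LynU_fwd"): {("activation", "full")},
            ("LynU_rev", "LynSH2_fwd"): {("activation", "full")},
            ("LynSH2_fwd", "LynU_rev"): {("inhibition", "partial"),
                                         ("activation", "partial")},
            ("LynU_fwd", "LynSH2_rev"): {("inhibition", "partial"),
                                         ("activation", "partial")},
            ("LynSH2_rev", "LynU_rev"): {("inhibition", "partial"),
                                         ("activation", "partial")},
            ("LynU_rev", "LynSH2_rev"): {("inhibition", "partial"),
                                         ("activation", "partial")},
        }
        assert got == expected


class TestGraph:
    def test_reversible_rules_split_into_two_nodes(self, lyn_correct):
        graph = build_influence_graph(lyn_correct)
        assert len(graph.nodes) == 8

    def test_two_disjoint_groups_reported_as_components(
            self, two_group_model):
        graph = build_influence_graph(two_group_model)
        comps = graph.components()
        assert len(comps) == 2
        sizes = sorted(len(c) for c in comps)
        assert sizes == [2, 2]

    def test_single_synthesis_rule_has_no_edges(self):
        model = parse_model("""
begin molecule types
  A(x)
end molecule types
begin reaction rules
  syn: 0 -> A(x) 1
end reaction rules
""")
        graph = build_influence_graph(model)
        assert len(graph.nodes) == 1 and graph.edges == []

    def test_self_influence_hidden_by_default(self, dimer_model):
        default = build_influence_graph(dimer_model)
        assert not any(s == d for s, d, _p, _t in default.edges)
        with_self = build_influence_graph(dimer_model, include_self=True)
        assert any(s == d for s, d, _p, _t in with_self.edges)

    def test_full_edge_suppresses_partial_of_same_polarity(self,
                                                           lyn_correct):
        graph = build_influence_graph(lyn_correct)
        seen = {}
        for src, dst, pol, strength in graph.edges:
            key = (src, dst, pol)
            assert key not in seen, "duplicate polarity on a pair"
            seen[key] = strength

    def test_degradation_only_model_has_inhibition_only(self):
        model = parse_model("""
begin molecule types
  A(x)
  B(y)
end molecule types
begin reaction rules
  degA: A() -> 0 1
  degAx: A(x) -> 0 1
end reaction rules
""")
        graph = build_influence_graph(model)
        assert graph.edges
        assert all(pol == "inhibition" for _s, _d, pol, _t in graph.edges)

    def test_synthesis_only_model_has_activation_only(self):
        model = parse_model("""
begin molecule types
  A(x)
end molecule types
begin reaction rules
  syn1: 0 -> A(x) 1
  syn2: 0 -> A(x) 2
end reaction rules
""")
        graph = build_influence_graph(model)
        assert all(pol == "activation" for _s, _d, pol, _t in graph.edges)

    def test_deleting_molecule_inhibits_requiring_rules(self):
        model = parse_model("""
begin molecule types
  A(x,y~U~P)
  B(z)
end molecule types
begin reaction rules
  deg: A() -> 0 1
  bind: A(x,y~P) + B(z) -> A(x!1,y~P).B(z!1) 1
end reaction rules
""")
        graph = build_influence_graph(model)
        rels = {(str(s), str(d), p, t) for s, d, p, t in graph.edges}
        # A() does not subsume A(x,y~P): partial inhibition
        assert ("deg_fwd", "bind_fwd", "inhibition", "partial") in rels
        model2 = parse_model("""
begin molecule types
  A(x,y~U~P)
  B(z)
end molecule types
begin reaction rules
  deg: A(x,y~P) -> 0 1
  bind: A(y~P) + B(z) -> A(y~P!1).B(z!1) 1
end reaction rules
""")
        graph2 = build_influence_graph(model2)
        rels2 = {(str(s), str(d), p, t) for s, d, p, t in graph2.edges}
        # the deleting pattern subsumes the requirement: full inhibition
        assert ("deg_fwd", "bind_fwd", "inhibition", "full") in rels2


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(60))
    def test_rule_influence_matches_exhaustive_overlap_oracle(self, seed):
        """On small random models the two-step relation computation equals
        an oracle that enumerates every sub-pattern overlap map."""
        model = random_model(FixtureSpec(seed=seed + 2000,
                                         n_molecule_types=3, n_rules=4))
        _assert_influence_matches_oracle(model)


def _assert_influence_matches_oracle(model):
    dirs = model.rule_directions()
    deltas = {rd: compute_delta(model.rule(rd.label), rd.direction)
              for rd in dirs}
    for r1 in dirs:
        rule1 = model.rule(r1.label)
        reactants1, products1 = rule1.sides(r1.direction)
        center_r = _center_on_side(deltas[r1], "reactant")
        center_p = _center_on_side(deltas[r1], "product")
        for r2 in dirs:
            rule2 = model.rule(r2.label)
            reactants2, _ = rule2.sides(r2.direction)
            got = rule_influence(rule1, r1.direction, rule2, r2.direction,
                                 deltas[r1])
            expected = set()
            for pol, pats, center in (("inhibition", reactants1, center_r),
                                      ("activation", products1, center_p)):
                best = None
                for p2 in reactants2:
                    for i1, p1 in enumerate(pats):
                        rel = pattern_relation_oracle(
                            p2, p1, center.slots.get(i1, set()),
                            center.mols.get(i1, set()))
                        if rel == "full":
                            best = "full"
                        elif rel == "partial" and best is None:
                            best = "partial"
                if best:
                    expected.add((pol, best))
            assert got == expected, (r1, r2)


class TestLinearOrder:
    def test_isolated_nodes_keep_declaration_order(self):
        model = parse_model("""
begin molecule types
  A(x)
  B(y)
end molecule types
begin reaction rules
  r1: 0 -> A(x) 1
  r2: 0 -> B(y) 1
end reaction rules
""")
        graph = build_influence_graph(model)
        order, layer = linear_order(graph)
        assert [str(n) for n in order] == ["r1_fwd", "r2_fwd"]
        assert all(v == "upper" for v in layer.values())

    def test_order_is_deterministic(self, lyn_correct):
        g1 = build_influence_graph(lyn_correct)
        g2 = build_influence_graph(lyn_fixture(True))
        assert [str(n) for n in linear_order(g1)[0]] == \
            [str(n) for n in linear_order(g2)[0]]

    def test_degree_sorts_before_declaration(self, two_group_model):
        graph = build_influence_graph(two_group_model)
        order, _ = linear_order(graph)
        degrees = [graph.degree(n) for n in order]
        assert degrees == sorted(degrees, reverse=True)

    def test_forward_nodes_upper_reverse_lower(self, lyn_correct):
        graph = build_influence_graph(lyn_correct)
        _, layer = linear_order(graph)
        for node in graph.nodes:
            assert layer[node] == ("upper" if node.direction == "forward"
                                   else "lower")
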