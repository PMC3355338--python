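"""Contact-map construction, bubble sets, compartments, orphans."""

import pytest

from rulemap.contact_map import (
    bubble_sets, build_contact_map, compartment_hierarchy, component_id,
    detect_orphans, hub_id, molecule_id, rules_for_edge, rules_for_state,
    state_id,
)
from rulemap.model import BnglError, RuleDir
from rulemap.parser import parse_model


@pytest.fixture(scope="module")
def ab_model():
    return parse_model("""
begin molecule types
  A(x,y~U~P)
end molecule types
begin seed species
  A(x,y~U) 10
end seed species
begin reaction rules
  dim: A(x) + A(x) <-> A(x!1).A(x!1) 1, 1
  phos: A(y~U) -> A(y~P) 1
end reaction rules
""")


class TestNodeInventory:
    def test_counts_follow_declarations(self, ab_model):
        cmap = build_contact_map(ab_model)
        assert cmap.molecule_nodes == [molecule_id("A")]
        assert set(cmap.component_nodes) == {component_id("A", "x"),
                                             component_id("A", "y")}
        assert set(cmap.state_nodes) == {state_id("A", "y", 0, "U"),
                                         state_id("A", "y", 0, "P")}

    def test_identical_sites_get_one_node_per_occurrence(self, ab_model):
        model = parse_model(
            "begin molecule types\n  Lig(l,l)\nend molecule types\n")
        cmap = build_contact_map(model)
        assert set(cmap.component_nodes) == {component_id("Lig", "l", 0),
                                             component_id("Lig", "l", 1)}

    def test_molecule_without_rules_has_no_edges(self):
        model = parse_model(
            "begin molecule types\n  A(x)\nend molecule types\n")
        cmap = build_contact_map(model)
        assert len(cmap.molecule_nodes) == 1
        assert len(cmap.component_nodes) == 1
        assert cmap.bond_edges == {}


class TestEdgesAndClasses:
    def test_symmetric_dimerization_self_edge_carries_both_directions(
            self, ab_model):
        cmap = build_contact_map(ab_model)
        key = frozenset([component_id("A", "x")])
        assert key in cmap.bond_edges
        assert cmap.bond_edges[key] == [RuleDir("dim", "forward"),
                                        RuleDir("dim", "reverse")]

    def test_state_change_classes(self, ab_model):
        cmap = build_contact_map(ab_model)
        assert cmap.node_class[component_id("A", "x")] == \
            "component_no_state"
        assert cmap.node_class[component_id("A", "y")] == \
            "component_state_change"
        assert cmap.node_class[state_id("A", "y", 0, "U")] == "state_changed"
        assert cmap.node_class[state_id("A", "y", 0, "P")] == "state_changed"

    def test_state_requiring_bond_rule_homes_edge_at_state_node(self):
        model = parse_model("""
begin molecule types
  R(y~U~P)
  G(sh2)
end molecule types
begin reaction rules
  bind: R(y~P) + G(sh2) -> R(y~P!1).G(sh2!1) 1
end reaction rules
""")
        cmap = build_contact_map(model)
        key = frozenset([state_id("R", "y", 0, "P"),
                         component_id("G", "sh2")])
        assert key in cmap.bond_edges

    def test_hub_node_for_degradation(self):
        model = parse_model("""
begin molecule types
  A(x)
end molecule types
begin reaction rules
  deg: A() -> 0 1
end reaction rules
""")
        cmap = build_contact_map(model)
        assert cmap.hub_nodes == {hub_id("deg"): [molecule_id("A")]}

    def test_every_bond_rule_direction_lands_on_exactly_one_edge(
            self, lyn_correct):
        from rulemap.patterns import classify_rule
        cmap = build_contact_map(lyn_correct)
        counted = [r for rules in cmap.bond_edges.values() for r in rules]
        bond_dirs = [rd for rd in lyn_correct.rule_directions()
                     if classify_rule(lyn_correct.rule(rd.label),
                                      rd.direction) == "bond_rule"]
        assert sorted(map(str, counted)) == sorted(map(str, bond_dirs))


class TestLynDebuggingScenario:
    def test_correct_and_incorrect_maps_are_indistinguishable(
            self, lyn_correct, lyn_incorrect):
        """Node and edge sets agree between the correct and incorrect
        formulations; only the bubble context reveals the error."""
        a = build_contact_map(lyn_correct)
        b = build_contact_map(lyn_incorrect)
        assert set(a.nodes()) == set(b.nodes())
        assert set(a.bond_edges) == set(b.bond_edges)

    @pytest.mark.parametrize("label,context_site", [
        ("LynSH2", "U"), ("LynU", "SH2")])
    def test_bubble_context_differs_exactly_in_the_free_site(
            self, lyn_correct, lyn_incorrect, label, context_site):
        rdir = RuleDir(label, "forward")
        good = bubble_sets(build_contact_map(lyn_correct), rdir)
        bad = bubble_sets(build_contact_map(lyn_incorrect), rdir)
        marker = component_id("Lyn", context_site)
        assert marker in good.context_nodes
        assert marker not in bad.context_nodes
        assert good.context_nodes - bad.context_nodes == {marker}
        assert good.center_nodes == bad.center_nodes

    def test_rec_lyn_edges_are_distinct(self, lyn_correct):
        cmap = build_contact_map(lyn_correct)
        e1 = frozenset([component_id("Rec", "b"),
                        component_id("Lyn", "SH2")])
        e2 = frozenset([component_id("Rec", "b"), component_id("Lyn", "U")])
        assert e1 in cmap.bond_edges and e2 in cmap.bond_edges
        assert rules_for_edge(cmap, e1) == [RuleDir("LynSH2", "forward"),
                                            RuleDir("LynSH2", "reverse")]


class TestQueries:
    def test_rules_for_state_includes_from_and_to(self, ab_model):
        cmap = build_contact_map(ab_model)
        for s in ("U", "P"):
            assert rules_for_state(cmap, state_id("A", "y", 0, s),
                                   ab_model) == [RuleDir("phos", "forward")]

    def test_unknown_edge_raises(self, ab_model):
        cmap = build_contact_map(ab_model)
        with pytest.raises(BnglError):
            rules_for_edge(cmap, frozenset(["C:A.z#0"]))

    def test_identity_rule_has_empty_center_bubble(self):
        model = parse_model("""
begin molecule types
  A(x)
end molecule types
begin reaction rules
  noop: A(x) -> A(x) 1
end reaction rules
""")
        cmap = build_contact_map(model)
        ann = bubble_sets(cmap, RuleDir("noop", "forward"))
        assert ann.center_nodes == set()

    def test_bubbles_project_delta_elements(self, lyn_correct):
        """Bubble node sets equal the projection of compute_delta output."""
        from rulemap.patterns import compute_delta
        cmap = build_contact_map(lyn_correct)
        rdir = RuleDir("LynSH2", "forward")
        delta = compute_delta(lyn_correct.rule("LynSH2"), "forward")
        ann = bubble_sets(cmap, rdir)
        assert ann.center_nodes == {component_id("Rec", "b"),
                                    component_id("Lyn", "SH2")}
        n_context_mols = sum(1 for el in delta.context if el[0] == "mol")
        assert {n for n in ann.context_nodes if n.startswith("M:")} == \
            {molecule_id("Rec"), molecule_id("Lyn")}
        assert n_context_mols == 2


class TestCompartments:
    def test_three_level_hierarchy_depths(self):
        model = parse_model("""
begin molecule types
  L()
  R()
end molecule types
begin compartments
  EC 3 1
  PM 2 1 EC
  CP 3 1 PM
end compartments
begin seed species
  @EC:L() 10
  @PM:R() 5
end seed species
""")
        tree = compartment_hierarchy(model)
        assert tree.depth == {"EC": 0, "PM": 1, "CP": 2}
        assert tree.members["EC"] == [molecule_id("L")]
        assert tree.members["PM"] == [molecule_id("R")]

    def test_no_compartments_gives_empty_tree(self, ab_model):
        tree = compartment_hierarchy(ab_model)
        assert tree.depth == {}

    def test_self_parent_cycle_is_an_error(self):
        with pytest.raises(BnglError):
            parse_model("begin compartments\n  X 3 1 X\nend compartments\n")


class TestOrphans:
    def test_unused_molecule_type_is_listed(self):
        model = parse_model("""
begin molecule types
  A(x)
  Ghost(g)
end molecule types
begin reaction rules
  r: A(x) + A(x) -> A(x!1).A(x!1) 1
end reaction rules
""")
        orphan_mols, _orphan_rules = detect_orphans(model)
        assert orphan_mols == [molecule_id("Ghost")]

    def test_fully_connected_lyn_model_has_no_orphans(self, lyn_correct):
        orphan_mols, orphan_rules = detect_orphans(lyn_correct)
        assert orphan_mols == [] and orphan_rules == []

    def test_two_group_model_has_no_orphan_rules_but_two_components(
            self, two_group_model):
        from rulemap.influence import build_influence_graph
        _mols, orphan_rules = detect_orphans(two_group_model)
        assert orphan_rules == []
        assert len(build_influence_graph(two_group_model).components()) == 2
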