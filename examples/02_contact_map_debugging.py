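"""Find a missing-context modeling error with bubble sets.

The correct and incorrect Lyn-binding formulations have *identical*
contact-map topology, so the plain map cannot reveal the bug.  The
per-rule reaction-context set can: the correct SH2-binding rule requires
the Lyn U site to be free (blue bubble), the incorrect one does not.
"""

from rulemap import build_contact_map, bubble_sets
from rulemap.contact_map import component_id
from rulemap.fixtures import lyn_fixture
from rulemap.model import RuleDir

good = build_contact_map(lyn_fixture(correct=True))
bad = build_contact_map(lyn_fixture(correct=False))

print("identical node sets:", set(good.nodes()) == set(bad.nodes()))
print("identical edge sets:", set(good.bond_edges) == set(bad.bond_edges))

rdir = RuleDir("LynSH2", "forward")
g = bubble_sets(good, rdir)
b = bubble_sets(bad, rdir)
print("correct context:", sorted(g.context_nodes))
print("incorrect context:", sorted(b.context_nodes))
marker = component_id("Lyn", "U")
print(f"missing element in the incorrect model: "
      f"{g.context_nodes - b.context_nodes} (the free-{marker} requirement "
      "that prevents Lyn from bridging two receptors)")
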