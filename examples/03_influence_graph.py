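"""Build the rule influence graph of the Lyn-binding model.

Nodes are unidirectional rules; edges carry activation/inhibition with
full/partial strength.  The two forward Lyn-binding rules mutually fully
inhibit each other (both consume Lyn with both sites free), and each
unbinding rule fully activates both binding rules.
"""

from rulemap import build_influence_graph
from rulemap.influence import linear_order
from rulemap.fixtures import lyn_fixture, two_group_fixture

graph = build_influence_graph(lyn_fixture(correct=True))
print(f"{len(graph.nodes)} rule directions, {len(graph.edges)} edges")
for src, dst, pol, strength in sorted(graph.edges, key=str):
    if "Lyn" in src.label and "Lyn" in dst.label:
        print(f"  {src} -> {dst}: {strength} {pol}")

order, layer = linear_order(graph)
print("arc-diagram order:", [str(n) for n in order])

# two molecule-disjoint rule groups signal a possibly incomplete model
split = build_influence_graph(two_group_fixture())
print("components in the two-group model:",
      len(split.components()))
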