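"""Generate reaction networks, including a bounded infinite chain.

The dimerization model reaches its 2-species fixpoint; the incorrect
Lyn-binding model polymerizes, so generation is truncated at the
aggregate-size bound and the species count keeps growing with it.
The reconstructed early-EGFR model reaches the published network size.
"""

from rulemap import generate_network, write_net
from rulemap.fixtures import dimer_fixture, egfr_fixture, lyn_fixture

net = generate_network(dimer_fixture())
print(f"dimer model: {len(net.species)} species, "
      f"{len(net.reactions)} reactions")
print(write_net(net))

bad = lyn_fixture(correct=False)
for max_agg in (2, 3, 4, 5):
    net = generate_network(bad, max_iter=30, max_agg=max_agg)
    print(f"max_agg={max_agg}: {len(net.species)} species "
          f"(truncated: {net.truncation_reason})")
# the strictly growing species count is the signature of an unbounded
# polymer — the modeling error the contact-map context reveals statically

egfr = generate_network(egfr_fixture(), max_iter=50, max_agg=20)
print(f"early-EGFR reconstruction: {len(egfr.species)} species, "
      f"{len(egfr.reactions)} unidirectional reactions")
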