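"""Parse a BNGL model and inspect its structure.

Builds the reduced Lyn-binding model (receptor Rec, kinase Lyn, bivalent
ligand Lig), prints its inventory and shows that serialization round-trips.
"""

from rulemap import parse_model, serialize_model
from rulemap.fixtures import lyn_fixture

model = lyn_fixture(correct=True)
print(f"model: {model.name}")
print(f"molecule types: {[mt.name for mt in model.molecule_types]}")
print(f"rules: {[r.label for r in model.rules]}")
print(f"seed species: {len(model.seed_species)}, "
      f"observables: {len(model.observables)}")

doc = serialize_model(model)
assert serialize_model(parse_model(doc)) == doc
print("parse -> serialize -> parse is a fixed point")
# The inventory lists the three proteins of the Lyn-binding exercise and
# its four reversible rules (ligand binding, crosslinking, two Lyn modes).
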