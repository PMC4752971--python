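"""Tanimoto similarity search over a synthetic library.

Builds a 200-compound scaffold-grammar library and searches it for
analogs of one member with path fingerprints at the Tc > 0.85 threshold
used for analog retrieval.
"""

from chemoprofile import FixtureConfig, similarity_search
from chemoprofile.fixtures import generate_library

library = generate_library(FixtureConfig(n_compounds=200))
query = library[14]  # an ethyl-benzofuran with several close decorations
hits = similarity_search(query, library, variant="path1024", threshold=0.85)

print(f"query: {query.compound_id} {query.smiles}")
print(f"{len(hits)} analogs with Tanimoto > 0.85 (query itself included):")
for compound_id, similarity in hits[:8]:
    print(f"  {compound_id}  Tc={similarity:.3f}")
print("\nTc = shared fingerprint bits / all set bits; 1.0 is the query itself,")
print("values near 0.9 are close decorations of the same scaffold.")
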