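"""Decompose a compound set into a scaffold forest.

Each molecule's ring framework is pruned one prioritized ring at a time
down to a single-ring root; chains from all compounds merge into a forest
used to order heatmap rows.
"""

from chemoprofile import Compound, build_forest
from chemoprofile.scaffolds import scaffold_chain

compounds = [
    Compound("flavone-like", "O=c1cc(-c2ccccc2)oc2ccccc12"),
    Compound("biphenyl", "c1ccc(-c2ccccc2)cc1"),
    Compound("toluene", "Cc1ccccc1"),
    Compound("octanol", "CCCCCCCCO"),
]

print("per-compound decomposition chains (leaf scaffold -> root):")
for c in compounds[:3]:
    print(f"  {c.compound_id}: " + "  ->  ".join(scaffold_chain(c)))

forest = build_forest(compounds)
print(f"\nforest: {len(forest.ring_roots)} ring roots, "
      f"{len(forest.acyclic_roots)} acyclic roots, {len(forest.index)} nodes")
print(forest.to_newick())
print("\nCompounds sharing a root (here benzene) sit together in heatmap rows;")
print("acyclic molecules live in their own partition.")
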