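"""Hierarchical ring-scaffold decomposition (scaffold trees).

A molecule's Murcko framework (ring systems plus linkers, side chains
stripped, exocyclic double-bonded atoms retained) is reduced one peripheral
ring at a time until a single ring remains; the resulting parent chains from
all compounds in a library are merged into a forest whose depth-first order
drives the heatmap row layout. Which ring to remove at each step is decided
by an ordered prioritization rule list with a final canonical-SMILES
tie-break, so decomposition is a total, deterministic function of structure.

Ring prioritization, applied in order until a single candidate parent
remains (a candidate = the scaffold left after deleting one peripheral
ring's exclusive atoms and re-Murcko-cleaning; candidates that disconnect
the scaffold are discarded):

1. remove three-membered heterocycles first;
2. keep macrocycles (>= 12 atoms) for last;
3. prefer the parent with the fewest acyclic linker bonds;
4. remove rings of size 3, 5 or 6 before other sizes;
5. remove rings with fewer heteroatoms first, precedence N > O > S;
6. remove smaller rings first;
7. tie-break on canonical SMILES of the parent (lexicographically smallest).

Acyclic molecules are handled by a separate deterministic pruning chain:
terminal heteroatoms are removed first, then terminal carbons off the
longest carbon chain, ending in the carbon backbone, which becomes a
level-0 root in a partition of the forest separate from ring chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .datatypes import Compound


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return mol


def num_rings(smiles: str) -> int:
    mol = _mol(smiles)  # keep the mol alive while the RingInfo proxy is used
    return mol.GetRingInfo().NumRings()


def murcko_scaffold(compound: Compound) -> Optional[str]:
    """Canonical Murcko framework SMILES, or None for acyclic molecules."""
    scaffold = MurckoScaffold.GetScaffoldForMol(_mol(compound.smiles))
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return None
    return Chem.MolToSmiles(scaffold)


# ---------------------------------------------------------------------------
# ring removal


def _linker_bond_count(mol: Chem.Mol) -> int:
    """Acyclic bonds between heavy atoms in a scaffold (linker bonds)."""
    return sum(1 for b in mol.GetBonds() if not b.IsInRing())


def _ring_heteroatoms(mol: Chem.Mol, ring: Sequence[int]) -> Tuple[int, int, int]:
    syms = [mol.GetAtomWithIdx(i).GetSymbol() for i in ring]
    return (syms.count("N"), syms.count("O"), syms.count("S"))


def _remove_ring(mol: Chem.Mol, ring: Sequence[int], other_ring_atoms: Set[int]) -> Optional[str]:
    """Delete one ring's exclusive atoms and Murcko-clean the remainder.

    Returns the canonical parent scaffold SMILES, or None when the ring is
    not removable (no exclusive atoms, disconnection, or chemistry that does
    not survive sanitization).
    """
    exclusive = [i for i in ring if i not in other_ring_atoms]
    if not exclusive:
        return None
    em = Chem.RWMol(mol)
    for idx in sorted(exclusive, reverse=True):
        em.RemoveAtom(idx)
    stripped = em.GetMol()
    try:
        Chem.SanitizeMol(stripped)
    except Exception:
        return None
    if len(Chem.GetMolFrags(stripped)) != 1:
        return None
    cleaned = MurckoScaffold.GetScaffoldForMol(stripped)
    if cleaned is None or cleaned.GetNumAtoms() == 0:
        return None
    return Chem.MolToSmiles(cleaned)


def scaffold_parent(scaffold_smiles: str) -> Optional[str]:
    """One prioritized ring-removal step; None once a single ring remains."""
    mol = _mol(scaffold_smiles)
    rings = mol.GetRingInfo().AtomRings()
    n = len(rings)
    if n == 0:
        raise ValueError(f"scaffold_parent requires a cyclic scaffold: {scaffold_smiles!r}")
    if n == 1:
        return None

    candidates = []  # (sort_key, parent_smiles)
    any_small = any(len(r) < 12 for r in rings)
    for i, ring in enumerate(rings):
        others: Set[int] = set()
        for j, other in enumerate(rings):
            if j != i:
                others.update(other)
        parent_smiles = _remove_ring(mol, ring, others)
        if parent_smiles is None:
            continue
        parent = _mol(parent_smiles)
        if parent.GetRingInfo().NumRings() != n - 1:
            continue
        n_het = _ring_heteroatoms(mol, ring)
        key = (
            0 if (len(ring) == 3 and sum(n_het) > 0) else 1,      # rule 1
            1 if (len(ring) >= 12 and any_small) else 0,          # rule 2
            _linker_bond_count(parent),                           # rule 3
            0 if len(ring) in (3, 5, 6) else 1,                   # rule 4
            n_het,                                                # rule 5
            len(ring),                                            # rule 6
            parent_smiles,                                        # rule 7 tie-break
        )
        candidates.append((key, parent_smiles))
    if not candidates:
        raise ValueError(
            f"no removable peripheral ring in {scaffold_smiles!r} (bridged system?)"
        )
    candidates.sort(key=lambda c: c[0])
    return candidates[0][1]


def scaffold_chain(compound: Compound) -> List[str]:
    """Full decomposition chain, leaf Murcko scaffold first, 1-ring root last.

    Empty for acyclic molecules (see :func:`decompose_acyclic`). For a
    k-ring molecule the chain has exactly k entries.
    """
    scaffold = murcko_scaffold(compound)
    if scaffold is None:
        return []
    chain = [scaffold]
    while True:
        parent = scaffold_parent(chain[-1])
        if parent is None:
            return chain
        chain.append(parent)


# ---------------------------------------------------------------------------
# acyclic decomposition


def _longest_carbon_chain(mol: Chem.Mol) -> Set[int]:
    """Atom indices of the longest simple carbon path (deterministic)."""
    carbons = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "C"]
    adj = {
        i: sorted(
            n.GetIdx()
            for n in mol.GetAtomWithIdx(i).GetNeighbors()
            if n.GetIdx() in set(carbons)
        )
        for i in carbons
    }
    best: Tuple[int, List[int]] = (0, [])

    def dfs(node: int, visited: List[int]) -> None:
        nonlocal best
        cand = (len(visited), visited)
        if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
            best = (cand[0], list(visited))
        for nxt in adj[node]:
            if nxt not in visited:
                visited.append(nxt)
                dfs(nxt, visited)
                visited.pop()

    for start in carbons:
        dfs(start, [start])
    return set(best[1])


def decompose_acyclic(compound: Compound) -> List[str]:
    """Pruning chain for a ring-free molecule, molecule first, backbone last.

    Each step removes one terminal atom — heteroatoms before carbons, and
    only carbons off the longest carbon chain — recording a fragment per
    removal. A molecule that is already a bare carbon chain maps to itself.
    """
    mol = Chem.RWMol(_mol(compound.smiles))
    if mol.GetRingInfo().NumRings() > 0:
        raise ValueError(f"decompose_acyclic requires an acyclic molecule: {compound.smiles!r}")
    chain = [Chem.MolToSmiles(mol)]
    while True:
        backbone = _longest_carbon_chain(mol)
        terminals = [
            a for a in mol.GetAtoms() if a.GetDegree() <= 1 and a.GetIdx() not in backbone
        ]
        if not terminals:
            return chain
        # heteroatoms first; deterministic pick by (is_carbon, symbol, index)
        terminals.sort(key=lambda a: (a.GetSymbol() == "C", a.GetSymbol(), a.GetIdx()))
        mol.RemoveAtom(terminals[0].GetIdx())
        Chem.SanitizeMol(mol)
        chain.append(Chem.MolToSmiles(mol))


# ---------------------------------------------------------------------------
# forest


@dataclass
class ScaffoldNode:
    """One node of the scaffold forest."""

    scaffold_smiles: str
    level: int  # ring count; 0 for acyclic-partition nodes
    parent: Optional[str] = None  # parent scaffold_smiles
    children: List[str] = field(default_factory=list)
    members: Set[str] = field(default_factory=set)


@dataclass
class ScaffoldForest:
    """Merged scaffold chains of a compound library.

    ``ring_roots`` are single-ring scaffolds; ``acyclic_roots`` are carbon
    backbones from the acyclic partition. ``index`` maps scaffold SMILES to
    the unique node carrying it.
    """

    index: Dict[str, ScaffoldNode] = field(default_factory=dict)
    ring_roots: List[str] = field(default_factory=list)
    acyclic_roots: List[str] = field(default_factory=list)

    @property
    def roots(self) -> List[str]:
        return sorted(self.ring_roots) + sorted(self.acyclic_roots)

    def leaf_of(self, compound_id: str) -> Optional[str]:
        """Scaffold SMILES of the deepest node containing this compound."""
        best = None
        for node in self.index.values():
            if compound_id in node.members:
                if best is None or node.level > best.level:
                    best = node
        return best.scaffold_smiles if best else None

    def depth_first_compounds(self) -> List[str]:
        """Compound ids in depth-first forest order.

        Siblings are visited in canonical-SMILES order; a node's own members
        (compounds whose leaf scaffold is that node) are listed in
        compound_id order before descending.
        """
        ordered: List[str] = []
        seen: Set[str] = set()

        def visit(smiles: str) -> None:
            node = self.index[smiles]
            own = node.members.difference(
                *(self.index[c].members for c in node.children)
            ) if node.children else set(node.members)
            for cid in sorted(own):
                if cid not in seen:
                    seen.add(cid)
                    ordered.append(cid)
            for child in sorted(node.children):
                visit(child)

        for root in self.roots:
            visit(root)
        return ordered

    def to_json_obj(self) -> dict:
        return {
            "ring_roots": sorted(self.ring_roots),
            "acyclic_roots": sorted(self.acyclic_roots),
            "nodes": [
                {
                    "scaffold_smiles": n.scaffold_smiles,
                    "level": n.level,
                    "parent": n.parent,
                    "children": sorted(n.children),
                    "members": sorted(n.members),
                }
                for n in sorted(self.index.values(), key=lambda n: (n.level, n.scaffold_smiles))
            ],
        }

    def to_newick(self) -> str:
        """Newick-like text rendering (labels = scaffold SMILES)."""

        def render(smiles: str) -> str:
            node = self.index[smiles]
            label = f"'{smiles}'"
            if not node.children:
                return label
            inner = ",".join(render(c) for c in sorted(node.children))
            return f"({inner}){label}"

        return ";\n".join(render(r) for r in self.roots) + ";"


def build_forest(compounds: Sequence[Compound]) -> ScaffoldForest:
    """Decompose every compound and merge the chains into one forest.

    Node identity is canonical scaffold SMILES; members propagate from each
    compound's leaf to every ancestor. Ring and acyclic chemistry live in
    separate partitions so a backbone never merges with a ring scaffold.
    """
    if not compounds:
        raise ValueError("build_forest requires at least one compound")
    forest = ScaffoldForest()

    def insert_chain(chain_root_last: List[str], levels: List[int], cid: str, ring: bool) -> None:
        # chain_root_last runs leaf -> root; insert root -> leaf
        parent_smiles: Optional[str] = None
        for smiles, level in zip(reversed(chain_root_last), reversed(levels)):
            node = forest.index.get(smiles)
            if node is None:
                node = ScaffoldNode(scaffold_smiles=smiles, level=level, parent=parent_smiles)
                forest.index[smiles] = node
                if parent_smiles is None:
                    (forest.ring_roots if ring else forest.acyclic_roots).append(smiles)
                else:
                    forest.index[parent_smiles].children.append(smiles)
            node.members.add(cid)
            parent_smiles = smiles

    for compound in sorted(compounds, key=lambda c: c.compound_id):
        chain = scaffold_chain(compound)
        if chain:
            levels = [num_rings(s) for s in chain]
            insert_chain(chain, levels, compound.compound_id, ring=True)
        else:
            acyclic = decompose_acyclic(compound)
            insert_chain(acyclic, [0] * len(acyclic), compound.compound_id, ring=False)
    for node in forest.index.values():
        node.children = sorted(set(node.children))
    return forest
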