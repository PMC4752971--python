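import random

import pytest
from rdkit import Chem

from chemoprofile.datatypes import Compound
from chemoprofile.scaffolds import (
    build_forest,
    decompose_acyclic,
    murcko_scaffold,
    num_rings,
    scaffold_chain,
    scaffold_parent,
)


def canon(smiles):
    return Chem.MolToSmiles(Chem.MolFromSmiles(smiles))


class TestMurckoScaffold:
    def test_side_chain_removed(self):
        assert murcko_scaffold(Compound("x", "Cc1ccccc1")) == canon("c1ccccc1")

    def test_bare_ring_is_fixed_point(self):
        assert murcko_scaffold(Compound("x", "c1ccccc1")) == canon("c1ccccc1")

    def test_acetophenone_carbonyl_side_chain_removed(self):
        # the carbonyl carbon is a side chain (not directly double-bonded to
        # the ring), so the framework is bare benzene
        assert murcko_scaffold(Compound("x", "CC(=O)c1ccccc1")) == canon("c1ccccc1")

    def test_exocyclic_double_bonded_atom_retained(self):
        # cyclohexanone: the =O is attached to a ring atom and stays
        assert murcko_scaffold(Compound("x", "O=C1CCCCC1")) == canon("O=C1CCCCC1")

    def test_acyclic_molecule_has_no_scaffold(self):
        assert murcko_scaffold(Compound("x", "CCO")) is None


class TestScaffoldParent:
    def test_single_ring_terminates(self):
        assert scaffold_parent("c1ccccc1") is None

    def test_biphenyl_reduces_to_benzene(self):
        assert scaffold_parent(canon("c1ccc(-c2ccccc2)cc1")) == canon("c1ccccc1")

    def test_pendant_five_ring_removed_before_fused_system(self):
        # fused 6-6 (naphthalene) plus a pendant cyclopentane: removing the
        # pendant ring leaves a parent with no linker bonds, so it goes first
        tricyclic = canon("C1CCC(c2ccc3ccccc3c2)C1")
        assert scaffold_parent(tricyclic) == canon("c1ccc2ccccc2c1")

    def test_acyclic_input_is_contract_error(self):
        with pytest.raises(ValueError):
            scaffold_parent("CCCC")

    @pytest.mark.parametrize(
        "smiles,k",
        [
            ("c1ccccc1", 1),
            ("c1ccc2ccccc2c1", 2),
            ("C1CCC2(CC1)CCCC2", 2),  # spiro
            ("c1ccc(-c2ccc(-c3ccccc3)cc2)cc1", 3),
            ("C1CCC(c2ccc3ccccc3c2)C1", 3),
            ("O=C(Nc1ccccc1)c1ccc(Cc2ccsc2)cc1", 3),
        ],
    )
    def test_chain_length_equals_ring_count(self, smiles, k):
        chain = scaffold_chain(Compound("x", smiles))
        assert len(chain) == k
        assert num_rings(chain[-1]) == 1
        # levels decrease by one ring per step
        assert [num_rings(s) for s in chain] == list(range(k, 0, -1))


class TestDecomposeAcyclic:
    def test_bare_chain_maps_to_itself(self):
        assert decompose_acyclic(Compound("x", "CC")) == ["CC"]

    def test_octanol_prunes_to_carbon_backbone(self):
        chain = decompose_acyclic(Compound("x", "CCCCCCCCO"))
        assert chain[0] == canon("CCCCCCCCO")
        assert chain[-1] == canon("CCCCCCCC")

    def test_branched_molecule_ends_in_longest_chain(self):
        chain = decompose_acyclic(Compound("x", "CC(C)CCO"))
        assert chain[-1] == canon("CCCC")

    def test_cyclic_input_is_contract_error(self):
        with pytest.raises(ValueError):
            decompose_acyclic(Compound("x", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"))  # caffeine


class TestBuildForest:
    def test_common_scaffold_merges_to_single_root(self):
        forest = build_forest(
            [
                Compound("a", "c1ccccc1"),
                Compound("b", "Cc1ccccc1"),
                Compound("c", "Oc1ccccc1"),
            ]
        )
        assert forest.ring_roots == [canon("c1ccccc1")]
        assert forest.index[forest.ring_roots[0]].members == {"a", "b", "c"}

    def test_disjoint_ring_systems_give_two_roots(self):
        forest = build_forest([Compound("a", "c1ccccc1"), Compound("b", "C1CCCC1")])
        assert len(forest.ring_roots) == 2

    def test_acyclic_compounds_live_in_their_own_partition(self):
        forest = build_forest([Compound("a", "c1ccccc1"), Compound("b", "CCCCO")])
        assert len(forest.ring_roots) == 1
        assert len(forest.acyclic_roots) == 1

    def test_grammar_library_has_exactly_five_ring_roots(self, medium_bundle):
        forest = build_forest(medium_bundle.library)
        assert len(forest.ring_roots) == 5
        assert not forest.acyclic_roots

    def test_every_compound_in_exactly_one_leaf_chain(self, small_bundle):
        forest = build_forest(small_bundle.library)
        for compound in small_bundle.library:
            leaf = forest.leaf_of(compound.compound_id)
            assert leaf is not None
            # membership holds along the whole ancestor chain, nowhere else
            node = forest.index[leaf]
            chain = set()
            while node is not None:
                chain.add(node.scaffold_smiles)
                assert compound.compound_id in node.members
                node = forest.index[node.parent] if node.parent else None
            for smiles, other in forest.index.items():
                if smiles not in chain:
                    sub = forest.index[smiles]
                    if compound.compound_id in sub.members:
                        # only descendants of the leaf may not contain it
                        assert False, f"{compound.compound_id} leaked into {smiles}"

    def test_input_order_permutation_yields_identical_forest(self, small_bundle):
        library = list(small_bundle.library)
        forest_a = build_forest(library)
        rng = random.Random(3)
        shuffled = list(library)
        rng.shuffle(shuffled)
        forest_b = build_forest(shuffled)
        assert set(forest_a.index) == set(forest_b.index)
        for smiles in forest_a.index:
            assert forest_a.index[smiles].members == forest_b.index[smiles].members
            assert forest_a.index[smiles].parent == forest_b.index[smiles].parent
        assert forest_a.depth_first_compounds() == forest_b.depth_first_compounds()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_forest([])
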