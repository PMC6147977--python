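"""Jaccard distances, neighbor joining, gene trees and consensus."""

import itertools

import numpy as np
import pytest

from phagekit.pangenome import GeneFamilyMatrix
from phagekit.phylo import (
    DistanceMatrix,
    UnrootedTree,
    cogrouping_consensus,
    core_gene_trees,
    jaccard_distances,
    neighbor_joining,
    rf_distance,
)
from phagekit.simulate import (
    GeneEvolutionParams,
    simulate_gene_tree_topologies,
    simulate_pangenome,
)

from conftest import random_additive_tree


def binary_matrix(sets, labels):
    families = sorted(set().union(*sets))
    m = np.array(
        [[1 if f in s else 0 for s in sets] for f in families]
    )
    return (labels, m)


class TestJaccard:
    @pytest.mark.parametrize(
        "sa, sb, expected",
        [
            ({1, 2, 3}, {1, 2, 3}, 0.0),
            ({1, 2}, {3, 4}, 1.0),
            ({1, 2, 3}, {2, 3, 4}, 0.5),
        ],
    )
    def test_pairwise_values(self, sa, sb, expected):
        dm = jaccard_distances(binary_matrix([sa, sb], ["A", "B"]))
        assert dm[("A", "B")] == pytest.approx(expected)

    def test_empty_vs_empty_warns_zero(self):
        with pytest.warns(UserWarning, match="empty family sets"):
            dm = jaccard_distances((["A", "B"], np.zeros((3, 2))))
        assert dm[("A", "B")] == 0.0

    def test_triangle_inequality_on_random_matrices(self, rng):
        for _ in range(20):
            pres = rng.integers(0, 2, size=(30, 5))
            pres[0] = 1  # avoid empty sets
            dm = jaccard_distances(([f"G{i}" for i in range(5)], pres))
            for i, j, k in itertools.permutations(range(5), 3):
                assert dm.d[i, j] <= dm.d[i, k] + dm.d[k, j] + 1e-12


class TestNeighborJoining:
    def test_exact_on_additive_five_leaf_tree(self, five_leaf_tree):
        labels = sorted(five_leaf_tree.leaf_labels())
        D = five_leaf_tree.path_length_matrix(labels)
        nj = neighbor_joining(DistanceMatrix(labels=labels, d=D))
        assert rf_distance(nj, five_leaf_tree) == 0
        np.testing.assert_allclose(
            nj.path_length_matrix(labels), D, atol=1e-9
        )

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
        nj = neighbor_joining(DistanceMatrix(labels=["A", "B", "C"], d=d))
        pl = nj.path_length_matrix(["A", "B", "C"])
        np.testing.assert_allclose(pl, d, atol=1e-12)
        # closed-form limb lengths: a=(dab+dac-dbc)/2 etc.
        tree = nj.dendropy_tree
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_matches_independent_nj_on_additive_matrices(self, rng):
        """Cross-check against scikit-bio's neighbor joining."""
        import io as _io

        from skbio import DistanceMatrix as SkbioDM, TreeNode
        from skbio.tree import nj as skbio_nj

        for trial in range(5):
            tree, labels = random_additive_tree(6, rng)
            labels = sorted(labels)
            D = tree.path_length_matrix(labels)
            mine = neighbor_joining(DistanceMatrix(labels=labels, d=D))
            theirs = skbio_nj(SkbioDM(D, ids=labels))
            theirs_uk = UnrootedTree.from_newick(str(theirs))
            assert rf_distance(mine, theirs_uk) == 0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=["A", "B"], d=np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError, match="NaN"):
            DistanceMatrix(
                labels=["A", "B"], d=np.array([[0, np.nan], [np.nan, 0]])
            )
        with pytest.raises(ValueError, match=">= 3"):
            neighbor_joining(
                DistanceMatrix(labels=["A", "B"], d=np.zeros((2, 2)))
            )


class TestRobinsonFoulds:
    def test_identity_and_distinct_quartets(self):
        a = UnrootedTree.from_newick("((A,B),(C,D));")
        b = UnrootedTree.from_newick("((A,C),(B,D));")
        assert rf_distance(a, a) == 0
        assert rf_distance(a, b) == 2

    def test_equals_dendropy_bipartition_comparison(self, rng):
        import dendropy
        from dendropy.calculate import treecompare

        for _ in range(10):
            t1, labels = random_additive_tree(7, rng)
            t2, _ = random_additive_tree(7, rng)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            expected = treecompare.symmetric_difference(d1, d2)
            assert rf_distance(t1, t2) == expected


class TestCherries:
    def test_cherry_enumeration(self):
        t = UnrootedTree.from_newick("((A,B),C,((D,E),F));")
        assert t.cherries() == {frozenset({"A", "B"}), frozenset({"D", "E"})}

    def test_quartet_has_two_cherries(self):
        t = UnrootedTree.from_newick("((A,B),(C,D));")
        assert t.cherries() == {frozenset({"A", "B"}), frozenset({"C", "D"})}


class TestCoreGeneTrees:
    def _matrix_and_set(self, seed=9, divergence=0.08):
        from phagekit.pangenome import cluster_orthologs

        gs = simulate_pangenome(
            GeneEvolutionParams(seed=seed, divergence=divergence, n_core=15)
        )
        return cluster_orthologs(gs), gs

    def test_majority_of_gene_trees_match_guide_topology(self):
        from phagekit.simulate import DEFAULT_GUIDE_TREE_NEWICK

        matrix, gs = self._matrix_and_set()
        guide = UnrootedTree.from_newick(DEFAULT_GUIDE_TREE_NEWICK)
        trees = core_gene_trees(matrix, gs)
        assert len(trees) >= 10
        match = sum(1 for t in trees if rf_distance(t, guide) == 0)
        assert match > len(trees) / 2

    def test_no_core_families_warns_empty(self):
        matrix = GeneFamilyMatrix(
            families=["F1"], genomes=["A", "B", "C"],
            counts=np.array([[1, 0, 1]]), membership={"F1": ["A|g1", "C|g1"]},
        )
        gs_like = simulate_pangenome(GeneEvolutionParams(seed=1, n_core=1))
        with pytest.warns(UserWarning, match="no single-copy core"):
            assert core_gene_trees(matrix, gs_like) == []


class TestConsensus:
    def test_identical_input_trees_reproduce_cherries(self):
        t = UnrootedTree.from_newick("((A,B),C,((D,E),F));")
        trees = [UnrootedTree.from_newick(t.to_newick()) for _ in range(111)]
        cgm, consensus = cogrouping_consensus(trees)
        i, j = cgm.labels.index("A"), cgm.labels.index("B")
        assert cgm.counts[i, j] == 111
        assert {frozenset({"A", "B"}), frozenset({"D", "E"})} <= consensus.cherries()

    def test_sister_pair_at_full_frequency_stays_sisters(self):
        trees = [
            UnrootedTree.from_newick("((A,B),(C,D));") for _ in range(60)
        ]
        cgm, consensus = cogrouping_consensus(trees)
        i, j = cgm.labels.index("A"), cgm.labels.index("B")
        assert cgm.counts[i, j] == 60
        assert frozenset({"A", "B"}) in consensus.cherries()

    def test_recovers_cherry_identifiable_guide_under_noise(self):
        """On a guide whose every split is a cherry the consensus is fully
        identifiable and recovers the topology under 20% NNI noise."""
        guide = UnrootedTree.from_newick("((A,B),(C,D),(E,F));")
        trees = simulate_gene_tree_topologies(guide, 111, 0.2, seed=21)
        _, consensus = cogrouping_consensus(trees)
        assert rf_distance(consensus, guide) == 0

    def test_recovers_guide_cherries_on_two_cherry_shape(self):
        """With two lone taxa only the guide's cherries are identifiable;
        they are always reproduced even when the deep attachment is not."""
        guide = UnrootedTree.from_newick("((A,B),C,((D,E),F));")
        trees = simulate_gene_tree_topologies(guide, 111, 0.2, seed=21)
        _, consensus = cogrouping_consensus(trees)
        assert guide.cherries() <= consensus.cherries()

    def test_invariant_to_tree_order(self):
        guide = UnrootedTree.from_newick("((A,B),C,((D,E),F));")
        trees = simulate_gene_tree_topologies(guide, 40, 0.3, seed=5)
        cgm1, c1 = cogrouping_consensus(trees)
        cgm2, c2 = cogrouping_consensus(list(reversed(trees)))
        np.testing.assert_array_equal(cgm1.counts, cgm2.counts)
        assert rf_distance(c1, c2) == 0

    def test_leaf_set_mismatch_rejected(self):
        a = UnrootedTree.from_newick("((A,B),(C,D));")
        b = UnrootedTree.from_newick("((A,B),(C,E));")
        with pytest.raises(ValueError, match="identical leaf set"):
            cogrouping_consensus([a, b])


class TestFingerprintPath:
    def test_band_matrix_flows_through_jaccard_nj(self, rng):
        """ERIC-PCR style band matrices use the same code path."""
        bands = rng.integers(0, 2, size=(25, 6))
        bands[:, 0] = bands[:, 1]  # two identical fingerprints
        bands[0] = 1
        labels = [f"S{i}" for i in range(6)]
        dm = jaccard_distances((labels, bands))
        assert dm[("S0", "S1")] == 0.0
        tree = neighbor_joining(dm)
        assert tree.leaf_labels() == set(labels)
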